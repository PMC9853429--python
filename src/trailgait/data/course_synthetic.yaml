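name: synthetic-trail-loop
labels:
- uphill
- top
- downhill
lengths_m:
- 580.0
- 520.0
- 470.0
slopes_deg:
- 4.0
- 2.0
- -6.0
waypoints:
- lat: 39.653
  lon: -105.192
  elevation: 1900.0
- lat: 39.653
  lon: -105.18522521419064
  elevation: 1940.557550927236
- lat: 39.65659423941311
  lon: -105.18911104927362
  elevation: 1958.7163510629448
- lat: 39.653
  lon: -105.192
  elevation: 1909.317360488077
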