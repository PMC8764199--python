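{
 "description": "Synthetic canonical microstate template maps (A-D) on the 19-channel 10-20 montage, constructed from schematic electrode positions; stand-ins for empirical grand-average templates, used only to order recovered prototypes.",
 "channel_names": [
  "Fp1",
  "Fp2",
  "F7",
  "F3",
  "Fz",
  "F4",
  "F8",
  "T3",
  "C3",
  "Cz",
  "C4",
  "T4",
  "T5",
  "P3",
  "Pz",
  "P4",
  "T6",
  "O1",
  "O2"
 ],
 "class_labels": [
  "A",
  "B",
  "C",
  "D"
 ],
 "maps": [
  [
   -0.17889701351227083,
   -0.3522030266022478,
   0.0614960046448549,
   -0.02795300211131828,
   -0.13976301055644033,
   -0.2627540198460746,
   -0.39133602955800273,
   0.27952602111288066,
   0.13976301055644033,
   -0.0,
   -0.13976301055644033,
   -0.27952602111288066,
   0.39133602955800273,
   0.2627540198460746,
   0.13976301055644033,
   0.02795300211131828,
   -0.0614960046448549,
   0.3522030266022478,
   0.17889701351227083
  ],
  [
   -0.35220302660224784,
   -0.17889701351227086,
   -0.3913360295580028,
   -0.2627540198460746,
   -0.13976301055644036,
   -0.027953002111318282,
   0.061496004644854906,
   -0.2795260211128807,
   -0.13976301055644036,
   0.0,
   0.13976301055644036,
   0.2795260211128807,
   -0.061496004644854906,
   0.027953002111318282,
   0.13976301055644036,
   0.2627540198460746,
   0.3913360295580028,
   0.17889701351227086,
   0.35220302660224784
  ],
  [
   -0.3702359120404731,
   -0.3702359120404731,
   -0.22993594537251438,
   -0.20265595185361263,
   -0.1948609537055247,
   -0.20265595185361263,
   -0.22993594537251438,
   -0.0,
   -0.0,
   -0.0,
   -0.0,
   -0.0,
   0.22993594537251438,
   0.20265595185361263,
   0.1948609537055247,
   0.20265595185361263,
   0.22993594537251438,
   0.3702359120404731,
   0.3702359120404731
  ],
  [
   -0.09670305476063454,
   -0.09670305476063454,
   -0.1391040787713236,
   0.18064210229331606,
   0.4064382301562804,
   0.18064210229331606,
   -0.1391040787713236,
   -0.18767710627707113,
   0.22196112569129398,
   0.5640263193946585,
   0.22196112569129398,
   -0.18767710627707113,
   -0.22344312653051573,
   -0.04494802545299527,
   0.08529604830111871,
   -0.04494802545299527,
   -0.22344312653051573,
   -0.23860813511809856,
   -0.23860813511809856
  ]
 ]
}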