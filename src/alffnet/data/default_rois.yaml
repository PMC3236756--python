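# Default seed regions: nine 6-mm spheres in MNI mm, three per network set.
# DMN = default-mode network, TPN = task-positive network, SN = sensory networks.
- {name: PCC,   set: DMN, x: 0,   y: -56, z: 30, radius: 6.0}   # posterior cingulate cortex
- {name: DMPFC, set: DMN, x: 0,   y: 54,  z: 30, radius: 6.0}   # dorsal medial prefrontal cortex
- {name: AG,    set: DMN, x: -45, y: -66, z: 30, radius: 6.0}   # left angular gyrus
- {name: DLPFC, set: TPN, x: 42,  y: 45,  z: 26, radius: 6.0}   # right dorsolateral prefrontal cortex
- {name: IPL,   set: TPN, x: -20, y: -60, z: 54, radius: 6.0}   # left intraparietal lobule
- {name: FEF,   set: TPN, x: -26, y: 2,   z: 52, radius: 6.0}   # left frontal eye field
- {name: SC,    set: SN,  x: -50, y: -24, z: 46, radius: 6.0}   # left primary somatosensory cortex
- {name: VC,    set: SN,  x: -20, y: -84, z: -4, radius: 6.0}   # left primary visual cortex
- {name: AC,    set: SN,  x: -60, y: -18, z: 2,  radius: 6.0}   # left auditory cortex
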