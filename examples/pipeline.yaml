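# End-to-end synthetic pipeline configuration.
seed: 3
fps: 30
script:
  - [walk, 2.0]
  - [sit, 2.0]
rig:
  n_cameras: 62
  n_levels: 2
noise:
  pixel_sigma: 2.0
  outlier_prob: 0.10
  occlusion: true
refine: true
refine_weights: [1.0, 1.0]
keyframe_threshold_m: 0.15
knn_k: 15
ablation_counts: [2, 4, 8, 16, 32, 48]
pck_tolerance_m: 0.10
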