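# frozen default configuration (see docs/methods.md)
variant: yolov8n_seg
nc: 1
reg_max: 16
nm: 32
image_size: 640
backbone_dims:
- 24
- 48
- 96
- 192
backbone_depths:
- 1
- 2
- 2
- 1
stem_ch: 24
mlp_ratio: 4
dw_kernel: 7
neck_channels:
- 32
- 64
- 96
neck_blocks: 1
use_mhsa: true
mhsa_heads: 4
pos_enc: true
head_width: 104
proto_mid: 32
baseline_width:
- 16
- 32
- 64
- 128
- 256
baseline_depths:
- 1
- 2
- 2
- 1
baseline_nc: 80
baseline_npr: 64
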