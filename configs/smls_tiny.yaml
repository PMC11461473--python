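# frozen default configuration (see docs/methods.md)
variant: smls
nc: 1
reg_max: 16
nm: 16
image_size: 256
backbone_dims:
- 16
- 32
- 64
- 128
backbone_depths:
- 1
- 1
- 1
- 1
stem_ch: 16
mlp_ratio: 4
dw_kernel: 7
neck_channels:
- 32
- 64
- 128
neck_blocks: 1
use_mhsa: true
mhsa_heads: 4
pos_enc: true
head_width: 32
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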