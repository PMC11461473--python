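"""Search the StarNet-S1-style config family for the default SMLS config.

Component parameter counts are cached so the search is fast; GFLOPs are
measured by a real forward pass only for parameter-feasible candidates.
Feasibility bands: total params in [1.695, 1.705) M, head params in
[0.245, 0.255) M, GFLOPs at 640 in [8.15, 8.25).
"""
import itertools
import numpy as np
from smlsyolo.model import ModelConfig, build_model
from smlsyolo.model_profile import count_gflops
from smlsyolo.star_backbone import StarNet
from smlsyolo.neck import Neck
from smlsyolo.segment_ls_head import SegmentLS

rng = np.random.default_rng(0)
bb_cache, neck_cache, head_cache = {}, {}, {}

def bb_params(dims, depths, stem):
    key = (dims, depths, stem)
    if key not in bb_cache:
        bb_cache[key] = StarNet(rng, dims, depths, stem).num_params()
    return bb_cache[key]

def neck_params(dims, neck):
    key = (dims, neck)
    if key not in neck_cache:
        neck_cache[key] = Neck(rng, dims[1:], neck, inner="star").num_params()
    return neck_cache[key]

def head_params(neck, W, M):
    key = (neck, W, M)
    if key not in head_cache:
        head_cache[key] = SegmentLS(rng, neck, W, 1, 16, 32, M).num_params()
    return head_cache[key]

cands = []
dims_opts = [(24,48,96,192),(16,32,64,128)]
for dims in dims_opts:
    neck_opts = [(n3,n4,n5) for n3 in (32,48,64) for n4 in (64,80,96,112,128)
                 for n5 in (96,128,160,192)]
    heads = [(n,W,M) for n in neck_opts for W in (64,72,80,88,96,104,112)
             for M in (32,40,48,56,64,72,80) if 245000 <= head_params(n,W,M) < 255000]
    for depths in itertools.product((1,2),(1,2),(1,2,3,4,5,6),(1,2)):
        for stem in (16,24,32):
            bb = bb_params(dims, depths, stem)
            if bb > 1460000:
                continue
            for (n,W,M) in heads:
                hp = head_params(n,W,M)
                tot = bb + neck_params(dims,n) + hp
                if 1695000 <= tot < 1705000:
                    cands.append((dims,depths,stem,n,W,M,tot,hp))
print("param-feasible:", len(cands))
hits = []
for dims,depths,stem,n,W,M,tot,hd in cands:
    cfg = ModelConfig(variant="smls", backbone_dims=dims, backbone_depths=depths,
                      stem_ch=stem, neck_channels=n, head_width=W, proto_mid=M)
    g = count_gflops(build_model(cfg, seed=0), 640)
    flag = "  <<<" if 8.15 <= g < 8.25 else ""
    if flag:
        hits.append((dims,depths,stem,n,W,M,tot,hd,g))
    print(f"dims={dims} depths={depths} stem={stem} neck={n} W={W} M={M} "
          f"tot={tot} head={hd} frac={100*hd/tot:.1f} gflops={g:.3f}{flag}")
print("\nGFLOP hits:", len(hits))
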