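"""Relative expression by the comparative threshold-cycle (2^-ddCt) method.

Computes the fold change of a target transcript between an experimental and a
control condition, normalized to a reference gene (tubulin), with replicate
Cts summarized by their mean and the ddCt standard error propagated.
"""
from motifarch import DdctMeasurement, ddct_fold_change

# single Cts: target drops from 22 to 20 cycles while the reference is stable
worked = ddct_fold_change(DdctMeasurement(
    ct_target_exp=20, ct_ref_exp=18, ct_target_ctrl=22, ct_ref_ctrl=18,
))
print(f"ddCt = {worked.delta_delta_ct:+.1f}  ->  fold change = {worked.fold:.1f}")
# ddCt = -2 means the target needs two fewer cycles relative to the
# reference in the experimental condition: 2^2 = 4-fold more transcript.

# triplicate Cts: same means, now with an uncertainty on ddCt
replicated = ddct_fold_change(DdctMeasurement(
    ct_target_exp=[20.0, 20.3, 19.7],
    ct_ref_exp=[18.0, 18.1, 17.9],
    ct_target_ctrl=[22.1, 21.9, 22.0],
    ct_ref_ctrl=[18.0, 18.0, 18.0],
))
lo, hi = replicated.fold_interval
print(
    f"replicates: fold = {replicated.fold:.2f}, "
    f"SE(ddCt) = {replicated.se_delta_delta_ct:.3f}, "
    f"fold range at +/-1 SE = [{lo:.2f}, {hi:.2f}]"
)
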