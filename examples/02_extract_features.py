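"""Filter, segment and featurize a record into the per-beat matrix.

Each beat becomes one row of 131 features (360 Hz profile): an LBP
pattern histogram (60), subsegment skewness/kurtosis (12), the 5th
central moment (1), Hermite expansion coefficients (16), level-3 Haar
approximation coefficients (32) and RR timing context (10).
"""

from ecgmpa import SimConfig, extract_all, generate_record
from ecgmpa.features import profile_for

record = generate_record(SimConfig(n_beats=120, seed=3))
profile = profile_for(record.fs)
matrix = extract_all(record, profile)

print(f"feature matrix: {matrix.shape[0]} beats x {matrix.shape[1] - 1} features")
print(f"block widths: {profile.block_widths()}")

first = matrix.iloc[0]
print(f"first beat ({first['label']}):")
print(f"  LBP histogram sums to {first.filter(like='lbp_').sum():.6f}")
print(f"  pre-RR {first['rr_00']:.3f} s, post-RR {first['rr_01']:.3f} s")
print(f"  largest Hermite coefficient {first.filter(like='hbf_').abs().max():.3f}")
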