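"""Factor space: the nine uncertain inputs and their distributions.

Builds the default factor set, draws values through the inverse CDFs, and
fixes the offer cap the way the model-simplification procedures do.
"""

from fallowsim import (
    factor_median,
    fix_factor,
    inverse_cdf,
    make_default_factors,
    transform_row,
)

specs = make_default_factors()
print("factor space:")
for s in specs:
    fixed = f" fixed={s.fixed_value}" if s.is_fixed else ""
    print(f"  {s.name:<11s} {s.kind:<22s} support[{s.support[0]}..{s.support[-1]}]{fixed}")

print("\ninverse-CDF draws at u=0.05 / 0.50 / 0.95:")
for s in specs:
    vals = [inverse_cdf(s, u) for u in (0.05, 0.50, 0.95)]
    print(f"  {s.name:<11s} {vals}")

fixed = fix_factor(specs, "n", 23)
fv = transform_row(fixed, [0.5] * 8)
print(f"\nafter fixing n at its median {factor_median(specs[-1])}:")
print(f"  free factors: {fv.free_names}")
print(f"  transformed row values: {fv.values}")
# Each draw maps a quasi-random unit-interval coordinate to a factor value;
# a fixed factor no longer consumes a coordinate, shrinking the design space.
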