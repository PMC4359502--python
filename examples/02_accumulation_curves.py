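"""Pan/core accumulation curves, Heaps-law fit and openness verdict.

Accumulates gene-family counts over random genome addition orders, fits
y = A·x^B + C to the pan curve and y = A·e^(B·x) + C to the core curve,
and reports whether the pan-genome is open (0 < B < 1).
"""

from panprev import (
    SimConfig,
    accumulate,
    build_matrix,
    classify_openness,
    extrapolate,
    fit_exponential,
    fit_power_law,
    generate_collection,
    greedy_cluster,
    remove_paralogs,
)
from panprev.io import collection_proteins

config = SimConfig(
    n_genomes=8,
    niche_assignment={f"G{i}": ("GIT" if i % 2 else "ORAL") for i in range(8)},
    n_core=25,
    n_shared_accessory=20,
    n_singletons=6,
    seed=13,
)
records, _ = generate_collection(config)
families = remove_paralogs(
    greedy_cluster(collection_proteins(records), prescreen_min_kmers=1)
)
matrix = build_matrix(families, {r.genome_id: r.niche for r in records})

pan, core, mean_new = accumulate(matrix, n_permutations=500, seed=3)
print("k, pan median, core median:")
for p, c in zip(pan, core):
    print(f"  {p.x:2d}  {p.y_median:7.1f}  {c.y_median:6.1f}")
print(f"mean new gene families per added genome: {mean_new:.1f}")

pan_fit = fit_power_law(pan)
core_fit = fit_exponential(core)
print(f"pan fit: A={pan_fit.A:.1f} B={pan_fit.B:.3f} C={pan_fit.C:.1f} "
      f"r²={pan_fit.r_squared:.4f} → {classify_openness(pan_fit)}")
print(f"core fit: A={core_fit.A:.1f} B={core_fit.B:.3f} C={core_fit.C:.1f} "
      f"r²={core_fit.r_squared:.4f}")
if core_fit.B < 0:
    # the asymptote C is the predicted stable core size as genomes are added
    print(f"predicted core-genome asymptote: {extrapolate(core_fit, 'asymptote'):.0f}")
print(f"pan size extrapolated at n={matrix.n_genomes}: "
      f"{extrapolate(pan_fit, matrix.n_genomes):.0f}")
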