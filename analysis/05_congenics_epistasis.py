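"""Dissect per-segment effects and epistasis with congenic strains.

Compares each single-segment congenic (and heterozygous carriers) with
the parental strains to call the mode of inheritance, then tests the
bicongenic combinations for epistatic suppression: the Chr13 segment,
null on its own, collapses the Chr1 effect when combined with it.
Finishes with the size analysis showing shape differences are not
size-driven.
"""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from morphoqtl import pipeline, simulate as sim, stats

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 43


def pairwise_d2(pc, groups, pairs, n_comparisons):
    rows = []
    for a, b in pairs:
        res = stats.hotelling_t2(
            pc[(groups == a).to_numpy()],
            pc[(groups == b).to_numpy()],
            n_comparisons=n_comparisons,
        )
        rows.append({"group_a": a, "group_b": b, "D2": res.d2, "T2": res.t2,
                     "p_raw": res.p_raw, "p_bonferroni": res.p_bonferroni})
    return pd.DataFrame(rows)


def main():
    cfg = sim.congenic_config(seed=SEED)
    # add heterozygous carriers for the mode-of-inheritance calls
    for locus in ("Chr1", "Chr13", "Chr18"):
        cfg.groups.append(sim.GroupSpec(f"{locus}H", f"congenic:{locus}:het", 12))
    ds = sim.generate_dataset(cfg)
    mat, _, _ = pipeline.coefficient_matrix(ds.outlines)
    groups = ds.design.set_index("id")["group"].reindex(mat.index)
    space = stats.pca_fit(mat.to_numpy(), 15)
    pc = pd.DataFrame(space.scores, index=mat.index)

    strains = ["B6", "66H", "Chr1", "Chr13", "Chr18"]
    pairs = list(combinations(strains, 2))
    d2 = pairwise_d2(pc, groups, pairs, len(pairs))
    print("pairwise Mahalanobis D² (15 PCs), congenics vs parents:")
    print(d2.round(3).to_string(index=False))

    print("\nmode of inheritance (heterozygote vs homozygote vs B6,")
    print("called from which pairwise Hotelling tests reject at 5%):")
    for locus in ("Chr1", "Chr13", "Chr18"):
        sub = pairwise_d2(
            pc, groups, [(f"{locus}H", "B6"), (f"{locus}H", locus), (locus, "B6")], 3
        ).set_index(["group_a", "group_b"])
        sig_het_b6 = sub.loc[(f"{locus}H", "B6"), "p_raw"] < 0.05
        sig_het_hom = sub.loc[(f"{locus}H", locus), "p_raw"] < 0.05
        sig_hom_b6 = sub.loc[(locus, "B6"), "p_raw"] < 0.05
        if not sig_hom_b6:
            call = "no individual effect"
        elif not sig_het_b6 and sig_het_hom:
            call = "donor allele recessive (het = B6)"
        elif not sig_het_hom and sig_het_b6:
            call = "donor allele dominant (het = homozygote)"
        elif sig_het_b6 and sig_het_hom:
            call = "codominant (het intermediate)"
        else:  # het separates from neither side: lean on the distances
            closer_hom = (
                sub.loc[(f"{locus}H", locus), "D2"]
                < sub.loc[(f"{locus}H", "B6"), "D2"]
            )
            call = ("dominant-leaning (het closer to homozygote)"
                    if closer_hom else "recessive-leaning (het closer to B6)")
        print(f"  {locus}: p(het,B6)={sub.loc[(f'{locus}H', 'B6'), 'p_raw']:.3f} "
              f"p(het,hom)={sub.loc[(f'{locus}H', locus), 'p_raw']:.3f} "
              f"p(hom,B6)={sub.loc[(locus, 'B6'), 'p_raw']:.3f} -> {call}")

    print("\nbicongenic epistasis (suppression of Chr1 by Chr13):")
    epi = pairwise_d2(
        pc, groups,
        [("Chr1", "B6"), ("Chr1+13", "B6"), ("Chr1+13", "Chr13"),
         ("Chr13+18", "Chr18"), ("Chr1+18", "66H")],
        5,
    )
    print(epi.round(3).to_string(index=False))
    d2s = epi.set_index(["group_a", "group_b"])["D2"]
    print(f"  D²(Chr1+13, B6) = {d2s[('Chr1+13','B6')]:.2f} << "
          f"D²(Chr1, B6) = {d2s[('Chr1','B6')]:.2f}: "
          "Chr13 abolishes most of the Chr1 effect")

    sizes = stats.size_table_and_anova(
        ds.outlines, ds.design["group"].to_numpy()
    )
    print(f"\nsize ANOVA across strains: F = {sizes['anova_f']:.2f}, "
          f"p = {sizes['anova_p']:.3f}")
    reg = stats.size_shape_regression(
        space.scores, [np.sqrt(pipeline.geometry.outline_area(o)) for o in ds.outlines]
    )
    print(f"15-PC multiple regression on size: omnibus R = "
          f"{reg['omnibus_R']:.3f}, p = {reg['omnibus_p']:.3g}")
    print("  (in this synthetic cohort genotype drives both outline shape and"
          " bone area, so a size-shape association is expected; the analysis"
          " machinery, not the biological decoupling, is what is exercised"
          " here)")

    RESULTS.mkdir(exist_ok=True)
    d2.to_csv(RESULTS / "05_congenic_d2.csv", index=False)
    epi.to_csv(RESULTS / "05_bicongenic_epistasis.csv", index=False)
    sizes["table"].to_csv(RESULTS / "05_size_table.csv", index=False)
    print(f"\ntables -> {RESULTS}")


if __name__ == "__main__":
    main()
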