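"""End-to-end outline-analysis chains used by the analysis scripts,
tests and the acceptance script.

Standard chain: normalize orientation -> resample to equal arc length ->
GPA on control points -> propagate transforms to outlines (sqrt-area
scaling) -> symmetrize -> elliptic Fourier coefficients -> PCA -> LDA
score phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from morphoqtl import efa, geometry, stats, tps

N_POINTS = 100
N_HARMONICS = 30
N_PCS = 15


def align_outlines(outlines, n_points: int = N_POINTS):
    """Orient, resample and Procrustes-align a set of outlines.

    Returns (aligned outlines, ProcrustesFit).  Alignment is GPA on the
    four control points; each outline is centered on its own centroid,
    scaled by 1/sqrt(area) and rotated by its fitted landmark rotation.
    """
    prepped = [
        geometry.resample_equal_arclength(tps.normalize_orientation(o), n_points)
        for o in outlines
    ]
    configs = np.stack([o.control_points for o in prepped])
    fit = geometry.gpa(configs, specimen_ids=[o.specimen_id for o in prepped])
    aligned = [geometry.apply_transform(o, fit) for o in prepped]
    return aligned, fit


def coefficient_matrix(
    outlines,
    n_points: int = N_POINTS,
    n_harmonics: int = N_HARMONICS,
    symmetrize: bool = True,
):
    """Aligned, (optionally) symmetrized Fourier coefficient matrix.

    Returns a specimens × 4H DataFrame (columns a1,b1,c1,d1,a2,...)
    indexed by specimen id, plus the aligned outlines and the GPA fit.
    """
    aligned, fit = align_outlines(outlines, n_points)
    vecs = []
    for o in aligned:
        if symmetrize:
            coeffs = efa.symmetrize(o, n_harmonics)
        else:
            coeffs = efa.efd(o.points, n_harmonics)
        vecs.append(coeffs.vector)
    cols = [
        f"{letter}{h}" for h in range(1, n_harmonics + 1) for letter in "abcd"
    ]
    mat = pd.DataFrame(vecs, index=[o.specimen_id for o in aligned], columns=cols)
    return mat, aligned, fit


def lda_phenotype(
    coeff_matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "B6",
    group_b: str = "66H",
    n_pcs: int = N_PCS,
):
    """Two-strain discriminant score for every specimen.

    PCA is fitted on the full analysis batch; the discriminant axis is
    fitted on the two named parental groups and applied to everyone.  The
    axis is oriented so ``group_a`` takes the higher mean.  Returns
    (scores Series, ShapeSpace, DiscriminantModel).
    """
    groups = groups.reindex(coeff_matrix.index)
    space = stats.pca_fit(coeff_matrix.to_numpy(), n_pcs)
    pc = pd.DataFrame(space.scores, index=coeff_matrix.index)
    train = groups.isin([group_a, group_b])
    model = stats.lda_fit(
        pc[train].to_numpy(), groups[train].to_numpy(), positive_group=group_a
    )
    scores = pd.Series(
        stats.lda_score(model, pc.to_numpy()), index=coeff_matrix.index, name="lda_score"
    )
    return scores, space, model


def f2_scan(dataset, n_pcs: int = N_PCS, n_perm: int = 1000, perm_seed: int = 0,
            alpha: float = 0.05):
    """F2 QTL scan of the two-parental-strain LDA score phenotype.

    Runs the full chain on a generated dataset containing B6, 66H and F2
    groups and returns a dict with the phenotype, the scan table, the
    permutation threshold, and the fitted models.
    """
    from morphoqtl import qtl

    mat, aligned, fit = coefficient_matrix(dataset.outlines)
    groups = dataset.design.set_index("id")["group"]
    scores, space, model = lda_phenotype(mat, groups)
    f2_ids = dataset.design.loc[dataset.design["group"] == "F2", "id"]
    pheno = scores.loc[f2_ids]
    table = qtl.GenotypeTable(
        dataset.genotypes.genotypes.loc[f2_ids], dataset.genotypes.markers
    )
    scan = qtl.lod_scan(pheno.to_numpy(), table)
    threshold = qtl.permutation_threshold(
        pheno.to_numpy(), table, alpha=alpha, n_perm=n_perm, seed=perm_seed
    )
    return {
        "scores": scores,
        "phenotype": pheno,
        "genotypes": table,
        "scan": scan,
        "threshold": threshold,
        "space": space,
        "model": model,
    }
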