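"""Marker-based QTL analysis of a quantitative shape phenotype.

Genotypes at microsatellite/SNP markers are observed directly, so the
single-QTL model is fitted by marker regression (a 3-class genotype
model), not by hidden-Markov interval mapping.  The LOD at a marker is

    LOD = (n/2) * log10(RSS0 / RSS1)

with RSS0 about the grand mean and RSS1 from the genotype-class model.
Genome-wide significance comes from phenotype permutations, the R/qtl
convention.  Missing genotypes are handled per marker by complete-case
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GENOTYPE_CODES = ("B/B", "B/S", "S/S")
#: donor (SEG) allele count per genotype code
SEG_DOSE = {"B/B": 0, "B/S": 1, "S/S": 2}
MISSING = "-"


@dataclass
class GenotypeTable:
    """Individuals × markers genotype matrix with marker map positions.

    ``genotypes``: DataFrame indexed by individual id, one column per
    marker, entries in {B/B, B/S, S/S, '-'} ('-' = missing).
    ``markers``: DataFrame indexed by marker name with columns
    ``chromosome`` and ``position_Mb``.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self):
        missing_meta = [m for m in self.genotypes.columns if m not in self.markers.index]
        if missing_meta:
            raise ValueError(f"markers without map positions: {missing_meta}")
        self.markers = self.markers.loc[list(self.genotypes.columns)]
        if (self.markers["position_Mb"] < 0).any():
            raise ValueError("negative marker positions")
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            pos = np.sort(sub["position_Mb"].to_numpy())
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"chromosome {chrom}: marker positions not strictly increasing"
                )
        # keep marker columns in map order (chromosome, then position)
        order = self.markers.sort_values(
            ["chromosome", "position_Mb"], kind="stable"
        ).index
        self.genotypes = self.genotypes[list(order)]
        self.markers = self.markers.loc[list(order)]
        bad = set(np.unique(self.genotypes.to_numpy().astype(str))) - set(
            GENOTYPE_CODES
        ) - {MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def marker_names(self) -> list:
        return list(self.genotypes.columns)

    def dose(self, marker: str) -> np.ndarray:
        """SEG-allele count at a marker (NaN where missing)."""
        return self.genotypes[marker].map(SEG_DOSE).to_numpy(dtype=float)


def _class_stats(y: np.ndarray, g: np.ndarray):
    rows = {}
    for code in GENOTYPE_CODES:
        sel = y[g == code]
        rows[code] = {
            "n": len(sel),
            "mean": sel.mean() if len(sel) else np.nan,
            "sem": sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else np.nan,
        }
    return rows


def marker_anova(phenotype, genotypes_at_marker, marker: str = ""):
    """One-way ANOVA of the phenotype across genotype classes at a marker.

    Returns a dict with per-class n/mean/sem and the F and p of the
    genotype model, or None (with a warning) when fewer than two classes
    with >= 2 individuals are present.  Missing genotypes are dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotypes_at_marker, dtype=object).astype(str)
    keep = (g != MISSING) & np.isfinite(y)
    y, g = y[keep], g[keep]
    classes = [c for c in GENOTYPE_CODES if np.sum(g == c) >= 2]
    if len(classes) < 2:
        warnings.warn(f"marker {marker or '?'}: fewer than 2 genotype classes; skipped")
        return None
    F, p = sps.f_oneway(*[y[g == c] for c in classes])
    row = {"marker": marker, "n": len(y), "F": float(F), "p": float(p)}
    for code, st in _class_stats(y, g).items():
        tag = code.replace("/", "")
        row[f"mean_{tag}"] = st["mean"]
        row[f"sem_{tag}"] = st["sem"]
        row[f"n_{tag}"] = st["n"]
    return row


def _lod_from_classes(y: np.ndarray, g: np.ndarray):
    """LOD of the genotype-class model vs the grand-mean null."""
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = 0.0
    for c in np.unique(g):
        yc = y[g == c]
        rss1 += float(np.sum((yc - yc.mean()) ** 2))
    if rss0 == 0.0:  # constant phenotype: no variance to explain
        return 0.0, rss0, rss1
    if rss1 == 0.0:
        warnings.warn("perfect genotype fit: LOD reported as inf")
        return np.inf, rss0, rss1
    return n / 2.0 * np.log10(rss0 / rss1), rss0, rss1


def lod_scan(phenotype, table: GenotypeTable) -> pd.DataFrame:
    """Marker-regression LOD scan of a quantitative phenotype.

    Per marker: F and p from the genotype-class ANOVA, LOD from the RSS
    ratio, genotype-class means ± sem and per-class n.  Individuals
    missing a marker's genotype are dropped for that marker only.
    """
    y_all = np.asarray(phenotype, dtype=float)
    if len(y_all) != len(table.genotypes):
        raise ValueError("phenotype length does not match genotype table")
    if len(y_all) < 10:
        raise ValueError("need n >= 10 for a scan")
    rows = []
    for marker in table.marker_names:
        g = table.genotypes[marker].to_numpy(dtype=object).astype(str)
        keep = (g != MISSING) & np.isfinite(y_all)
        y, gg = y_all[keep], g[keep]
        lod, rss0, rss1 = _lod_from_classes(y, gg)
        row = {
            "marker": marker,
            "chromosome": table.markers.loc[marker, "chromosome"],
            "position_Mb": table.markers.loc[marker, "position_Mb"],
            "n": len(y),
            "lod": lod,
        }
        an = marker_anova(y, gg, marker=marker)
        if an is not None:
            an.pop("marker")
            an.pop("n")
            row.update(an)
        else:
            row.update({"F": np.nan, "p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_threshold(
    phenotype,
    table: GenotypeTable,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Genome-wide LOD significance threshold by phenotype permutation.

    Permutes the phenotype against the genotype rows ``n_perm`` times and
    returns the (1 - alpha) quantile of the per-permutation maximum LOD
    across markers.  Deterministic given ``seed``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])  # (P, n)
    max_lod = np.zeros(n_perm)
    for marker in table.marker_names:
        g = table.genotypes[marker].to_numpy(dtype=object).astype(str)
        keep = g != MISSING
        gm = g[keep]
        ym = perms[:, keep]  # (P, m)
        m = ym.shape[1]
        onehot = np.column_stack([(gm == c) for c in np.unique(gm)]).astype(float)
        counts = onehot.sum(axis=0)
        sums = ym @ onehot  # (P, classes)
        rss1 = np.sum(ym**2, axis=1) - np.sum(sums**2 / counts, axis=1)
        rss0 = np.sum(ym**2, axis=1) - ym.sum(axis=1) ** 2 / m
        with np.errstate(divide="ignore"):
            lod = m / 2.0 * np.log10(rss0 / np.maximum(rss1, 1e-300))
        max_lod = np.maximum(max_lod, lod)
    return float(np.quantile(max_lod, 1.0 - alpha))


def epistasis_anova(phenotype, geno_a, geno_b):
    """Two-way fixed-effects ANOVA with interaction between two markers.

    Type-II sums of squares (robust to empty/unbalanced cells); returns
    main-effect and interaction F and p.  Symmetric in factor order.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = np.asarray(phenotype, dtype=float)
    a = np.asarray(geno_a, dtype=object).astype(str)
    b = np.asarray(geno_b, dtype=object).astype(str)
    keep = (a != MISSING) & (b != MISSING) & np.isfinite(y)
    df = pd.DataFrame({"y": y[keep], "a": a[keep], "b": b[keep]})
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 populated levels")
    fit = ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return {
        "F_a": float(tab.loc["C(a)", "F"]),
        "p_a": float(tab.loc["C(a)", "PR(>F)"]),
        "F_b": float(tab.loc["C(b)", "F"]),
        "p_b": float(tab.loc["C(b)", "PR(>F)"]),
        "F_interaction": float(tab.loc["C(a):C(b)", "F"]),
        "p_interaction": float(tab.loc["C(a):C(b)", "PR(>F)"]),
        "n": int(len(df)),
    }


def allele_dose_profile(phenotype, geno_a, geno_b):
    """Phenotype mean ± sem per total donor-allele count (0–4) at two loci.

    Individuals missing either genotype are excluded.  Also reports the
    linear-trend regression (slope, t, p) of phenotype on dose.
    """
    y = np.asarray(phenotype, dtype=float)
    a = np.asarray(geno_a, dtype=object).astype(str)
    b = np.asarray(geno_b, dtype=object).astype(str)
    keep = (a != MISSING) & (b != MISSING) & np.isfinite(y)
    y = y[keep]
    dose = np.array([SEG_DOSE[x] for x in a[keep]]) + np.array(
        [SEG_DOSE[x] for x in b[keep]]
    )
    rows = []
    for d in range(5):
        sel = y[dose == d]
        rows.append(
            {
                "dose": d,
                "n": len(sel),
                "mean": sel.mean() if len(sel) else np.nan,
                "sem": sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else np.nan,
            }
        )
    res = sps.linregress(dose, y)
    return {
        "profile": pd.DataFrame(rows),
        "trend_slope": float(res.slope),
        "trend_t": float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        "trend_p": float(res.pvalue),
    }


def segment_sizes(table: GenotypeTable, boundaries: dict) -> pd.DataFrame:
    """Donor-segment sizes in Mb from boundary-marker positions.

    ``boundaries`` maps a segment name to its (left, right) boundary
    marker names; both must lie on one chromosome.  Sizes are reported
    raw and rounded to integer Mb.
    """
    rows = []
    for segment, (left, right) in boundaries.items():
        for m in (left, right):
            if m not in table.markers.index:
                raise KeyError(f"boundary marker {m!r} not in table")
        cl = table.markers.loc[left, "chromosome"]
        cr = table.markers.loc[right, "chromosome"]
        if cl != cr:
            raise ValueError(
                f"segment {segment!r}: boundary markers on different "
                f"chromosomes ({cl} vs {cr})"
            )
        size = abs(
            float(table.markers.loc[right, "position_Mb"])
            - float(table.markers.loc[left, "position_Mb"])
        )
        rows.append(
            {
                "segment": segment,
                "chromosome": cl,
                "size_Mb": size,
                "size_Mb_rounded": int(round(size)),
            }
        )
    return pd.DataFrame(rows)
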