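"""Synthetic outline/genotype generator emulating the study design.

The generator produces the data structures the analysis chain consumes,
with the statistical structure of the real experiment:

* ~100-point closed outlines of a bilaterally near-symmetric bone whose
  shape varies in caudal-notch depth, rostral/caudal width ratio and
  lateral depression, with four homologous control points;
* inbred groups (recipient "B6"-like, donor-segment carrier "66H"-like),
  their F1, an F2 intercross, and congenic/bicongenic strains carrying
  one or two donor segments;
* three unlinked donor segments (Chr1 ~31.5 Mb, Chr13 ~10.1 Mb, Chr18
  ~13.3 Mb) whose markers segregate with Haldane-map recombination at
  1 cM/Mb, with additive, dominance and epistatic (suppression) effects
  on the shape parameters plus per-individual Gaussian shape noise.

The outline is a smooth periodic parametric curve: a superellipse of
length L and caudal width Wc whose half-width tapers linearly to the
rostral width (ratio r), with a Gaussian notch indentation at the caudal
midline and a Gaussian lateral depression near the rostral end, resampled
to equal arc length.  Before noise it is exactly symmetric about the
x-axis; the rostral midline vertex is the anchor/start point.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing

from morphoqtl.tps import Outline, write_tps
from morphoqtl.geometry import resample_equal_arclength, _rot
from morphoqtl.qtl import GenotypeTable

PARAM_FIELDS = (
    "length",
    "caudal_width",
    "rostral_ratio",
    "notch_depth",
    "depression_amp",
    "corner_round",
)


@dataclass
class ShapeParams:
    """Geometric parameters of the synthetic bone outline.

    length, caudal_width: overall extent (arbitrary units).
    rostral_ratio: rostral/caudal width ratio (1 = rectangle, <1 =
    trapezoid).  notch_depth: caudal midline indentation as a fraction of
    length.  depression_amp: lateral inward concavity near the rostral
    end, fraction of the local half-width.  corner_round: corner smoothing
    (superellipse exponent 2/corner_round).  asymmetry_noise: s.d. of
    per-point radial digitizing noise; landmark_jitter: s.d. of
    independent control-point jitter.
    """

    length: float = 2.0
    caudal_width: float = 1.0
    rostral_ratio: float = 1.0
    notch_depth: float = 0.0
    depression_amp: float = 0.0
    corner_round: float = 0.25
    asymmetry_noise: float = 0.0
    landmark_jitter: float = 0.0

    def validate(self):
        if self.length <= 0 or self.caudal_width <= 0:
            raise ValueError("length and caudal_width must be positive")
        if not 0 < self.rostral_ratio <= 1.5:
            raise ValueError("rostral_ratio must be in (0, 1.5]")
        if not 0 <= self.notch_depth < 0.4:
            raise ValueError("notch_depth must be in [0, 0.4)")
        if not 0 <= self.depression_amp < 0.5:
            raise ValueError("depression_amp must be in [0, 0.5)")
        if not 0 < self.corner_round <= 1.0:
            raise ValueError("corner_round must be in (0, 1]")
        if self.asymmetry_noise < 0 or self.landmark_jitter < 0:
            raise ValueError("noise s.d. must be >= 0")
        return self

    def geometry_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    def with_geometry(self, vec: np.ndarray) -> "ShapeParams":
        vec = np.asarray(vec, dtype=float)
        # clip into the valid parameter region (noise may push outside)
        lo = np.array([1e-3, 1e-3, 1e-3, 0.0, 0.0, 1e-3])
        hi = np.array([np.inf, np.inf, 1.5, 0.399, 0.499, 1.0])
        vec = np.clip(vec, lo, hi)
        return replace(self, **dict(zip(PARAM_FIELDS, vec)))


@dataclass
class Locus:
    """A donor-derived chromosomal segment with its markers and effect."""

    name: str
    chromosome: str
    start_Mb: float
    end_Mb: float
    markers: list  # [(name, position_Mb), ...]
    effect: np.ndarray  # additive effect on the 6 geometry parameters
    dominance: float = 0.0  # 0 codominant, 1 donor-dominant, -1 donor-recessive
    causal_marker: str | None = None

    def __post_init__(self):
        self.effect = np.asarray(self.effect, dtype=float)
        if self.effect.shape != (len(PARAM_FIELDS),):
            raise ValueError(f"effect must have {len(PARAM_FIELDS)} entries")
        if not -1.0 <= self.dominance <= 1.0:
            raise ValueError("dominance coefficient must be in [-1, 1]")
        for mname, pos in self.markers:
            if not self.start_Mb <= pos <= self.end_Mb:
                raise ValueError(
                    f"marker {mname} at {pos} Mb outside segment "
                    f"[{self.start_Mb}, {self.end_Mb}]"
                )
        if self.causal_marker is None:
            self.causal_marker = self.markers[len(self.markers) // 2][0]

    @property
    def marker_names(self):
        return [m for m, _ in self.markers]


@dataclass
class EpistasisTerm:
    """Donor/donor homozygosity at ``modifier`` scales the ``target``
    locus's effect by (1 - suppression)."""

    modifier: str
    target: str
    suppression: float

    def __post_init__(self):
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression factor must be in [0, 1]")


@dataclass
class GeneticArchitecture:
    loci: list  # of Locus
    epistasis: list = field(default_factory=list)  # of EpistasisTerm
    residual_sd_shared: float = 0.0  # s.d. of shared noise along the effect axis
    residual_sd_indep: np.ndarray | None = None  # per-parameter independent noise

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for term in self.epistasis:
            if term.modifier not in names or term.target not in names:
                raise ValueError("epistasis term references unknown locus")
        if self.residual_sd_indep is not None:
            self.residual_sd_indep = np.asarray(self.residual_sd_indep, dtype=float)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def total_effect(self) -> np.ndarray:
        return np.sum([l.effect for l in self.loci], axis=0)


def dose(code: str, dominance: float = 0.0) -> float:
    """Donor-effect dose of a genotype code under a dominance coefficient.

    B/B -> 0, S/S -> 1, B/S -> (1 + dominance)/2 (0.5 when codominant).
    """
    if code == "B/B":
        return 0.0
    if code == "S/S":
        return 1.0
    if code == "B/S":
        return (1.0 + dominance) / 2.0
    raise ValueError(f"unknown genotype code {code!r}")


def genotype_to_params(
    genotype: dict, arch: GeneticArchitecture, base: ShapeParams
) -> ShapeParams:
    """Map per-locus genotype codes to expected shape parameters.

    params = base + Σ_l dose(g_l, dominance_l) · effect_l, where each
    locus's effect is first scaled by (1 - suppression) for every
    epistasis term whose modifier locus is donor-homozygous (S/S).
    """
    vec = base.geometry_vector()
    for locus in arch.loci:
        if locus.name not in genotype:
            raise KeyError(f"missing genotype for locus {locus.name!r}")
        eff = locus.effect.copy()
        for term in arch.epistasis:
            if term.target == locus.name and genotype.get(term.modifier) == "S/S":
                eff = eff * (1.0 - term.suppression)
        vec = vec + dose(genotype[locus.name], locus.dominance) * eff
    return base.with_geometry(vec)


# ---------------------------------------------------------------------------
# Outline construction

_DENSE = 1024
_NOTCH_WIDTH = 0.28  # rad, Gaussian width of the caudal notch in parameter t
_DEP_CENTER = 0.55  # depression center along +x, fraction of half-length
_DEP_WIDTH = 0.22  # depression width, fraction of half-length


def _parametric_curve(p: ShapeParams, n_dense: int = _DENSE) -> np.ndarray:
    """Noise-free closed curve, symmetric about the x-axis, rostral at +x.

    Only the upper half is evaluated; the lower half is its exact mirror,
    so bilateral symmetry holds to the last bit (the fractional
    superellipse power would otherwise amplify float noise near the axis
    crossings).
    """
    if n_dense % 2:
        raise ValueError("n_dense must be even")
    half = n_dense // 2
    t = np.linspace(0.0, np.pi, half + 1)  # upper half, endpoints on the axis
    m = 2.0 / p.corner_round
    a = p.length / 2.0
    ct, st = np.cos(t), np.sin(t)
    x = a * np.sign(ct) * np.abs(ct) ** (2.0 / m)
    # half-width tapers linearly from caudal (-x) to rostral (+x)
    frac = (x + a) / (2.0 * a)
    h = (p.caudal_width / 2.0) * (1.0 + (p.rostral_ratio - 1.0) * frac)
    # lateral depression near the rostral end
    h = h * (1.0 - p.depression_amp * np.exp(
        -(((x - _DEP_CENTER * a) / (_DEP_WIDTH * a)) ** 2)))
    y = h * np.abs(st) ** (2.0 / m)
    y[0] = y[-1] = 0.0  # exact axis crossings
    # caudal midline notch: indent the boundary inward around t = pi
    x = x + p.notch_depth * p.length * np.exp(-(((t - np.pi) / _NOTCH_WIDTH) ** 2))
    upper = np.column_stack([x, y])
    lower = upper[half - 1:0:-1] * np.array([1.0, -1.0])
    return np.vstack([upper, lower])


def make_outline(
    params: ShapeParams,
    n_points: int = 100,
    seed: int | np.random.Generator = 0,
    specimen_id: str = "",
    rotation_range: float = 0.0,
    translation_range: float = 0.0,
    scale_range: tuple = (1.0, 1.0),
) -> Outline:
    """Generate one synthetic outline with its four control points.

    The noise-free curve is exactly symmetric about the x-axis and starts
    at the rostral midline vertex; points are equally spaced along the
    arc.  Per-point radial noise (``asymmetry_noise``) and independent
    control-point jitter (``landmark_jitter``) are applied, then a random
    rigid nuisance motion (rotation, translation, global scale).  Control
    points: rostral midline, caudal midline (notch bottom), +y and -y
    maximal-width lateral points.  Deterministic given the seed.
    """
    params.validate()
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dense = _parametric_curve(params)
    if not LinearRing(dense).is_simple:
        raise ValueError(
            "self-intersecting outline: notch_depth "
            f"{params.notch_depth} with corner_round {params.corner_round} "
            "(and depression_amp "
            f"{params.depression_amp}) is too extreme"
        )
    pts = resample_equal_arclength(dense, n_points)

    # control points from the noise-free geometry
    cp_rostral = dense[0]
    cp_caudal = dense[len(dense) // 2]
    cp_lat_pos = dense[np.argmax(dense[:, 1])]
    cp_lat_neg = dense[np.argmin(dense[:, 1])]
    cps = np.vstack([cp_rostral, cp_caudal, cp_lat_pos, cp_lat_neg])

    if params.asymmetry_noise > 0:
        centroid = pts.mean(axis=0)
        radial = pts - centroid
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        pts = pts + params.asymmetry_noise * rng.standard_normal((n_points, 1)) * radial
    if params.landmark_jitter > 0:
        cps = cps + params.landmark_jitter * rng.standard_normal(cps.shape)

    theta = rng.uniform(-rotation_range, rotation_range) if rotation_range else 0.0
    shift = (
        rng.uniform(-translation_range, translation_range, size=2)
        if translation_range
        else np.zeros(2)
    )
    lo, hi = scale_range
    scale = rng.uniform(lo, hi) if hi > lo else lo
    R = _rot(theta)
    pts = scale * pts @ R.T + shift
    cps = scale * cps @ R.T + shift
    return Outline(pts, cps, specimen_id)


# ---------------------------------------------------------------------------
# Genotype simulation


def _haldane(d_Mb: float) -> float:
    """Recombination fraction from Mb distance at 1 cM/Mb (Haldane map)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_Mb / 100.0))


def _marker_map(arch: GeneticArchitecture) -> pd.DataFrame:
    rows = []
    for locus in arch.loci:
        for mname, pos in locus.markers:
            rows.append(
                {"marker": mname, "chromosome": locus.chromosome, "position_Mb": pos}
            )
    return pd.DataFrame(rows).set_index("marker")


def _f2_gametes(positions: np.ndarray, n: int, rng) -> np.ndarray:
    """n gametes (rows) of 0/1 donor alleles along one chromosome."""
    k = len(positions)
    alleles = np.zeros((n, k), dtype=int)
    alleles[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, k):
        r = _haldane(positions[j] - positions[j - 1])
        flip = rng.random(n) < r
        alleles[:, j] = np.where(flip, 1 - alleles[:, j - 1], alleles[:, j - 1])
    return alleles


def parse_design(design: str):
    """Parse a design label.

    Accepted: ``inbred_B6``, ``inbred_donor``, ``F1``, ``F2``,
    ``congenic:Chr1``, ``congenic:Chr1:het``,
    ``bicongenic:Chr1+Chr13`` (homozygous donor at both segments).
    """
    if design in ("inbred_B6", "inbred_donor", "F1", "F2"):
        return design, (), "hom"
    parts = design.split(":")
    if parts[0] == "congenic" and len(parts) in (2, 3):
        zyg = parts[2] if len(parts) == 3 else "hom"
        if zyg not in ("hom", "het"):
            raise ValueError(f"unknown zygosity {zyg!r}")
        return "congenic", tuple(parts[1].split("+")), zyg
    if parts[0] == "bicongenic" and len(parts) == 2:
        loci = tuple(parts[1].split("+"))
        if len(loci) != 2:
            raise ValueError("bicongenic design needs exactly two loci")
        return "congenic", loci, "hom"
    raise ValueError(f"unknown design label {design!r}")


def simulate_genotypes(
    arch: GeneticArchitecture, design: str, n: int, seed: int | np.random.Generator = 0
) -> GenotypeTable:
    """Genotypes at all architecture markers for ``n`` individuals.

    F2 loci on different chromosomes segregate independently; markers on
    one chromosome recombine with Haldane probability from their Mb
    distance at 1 cM/Mb.  Inbred, F1 and congenic designs return fixed
    genotypes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind, loci_sel, zygosity = parse_design(design)
    markers = _marker_map(arch)
    cols = {}
    if kind == "F2":
        for locus in arch.loci:
            pos = np.array([p for _, p in locus.markers])
            g = _f2_gametes(pos, n, rng) + _f2_gametes(pos, n, rng)
            for j, mname in enumerate(locus.marker_names):
                cols[mname] = np.array(["B/B", "B/S", "S/S"])[g[:, j]]
    else:
        for locus in arch.loci:
            if kind == "inbred_B6":
                code = "B/B"
            elif kind == "inbred_donor":
                code = "S/S"
            elif kind == "F1":
                code = "B/S"
            else:  # congenic
                if locus.name in loci_sel:
                    code = "S/S" if zygosity == "hom" else "B/S"
                else:
                    code = "B/B"
            for mname in locus.marker_names:
                cols[mname] = np.repeat(code, n)
    ids = [f"ind_{i + 1}" for i in range(n)]
    geno = pd.DataFrame(cols, index=ids)
    return GenotypeTable(geno, markers)


# ---------------------------------------------------------------------------
# Full dataset generation


@dataclass
class GroupSpec:
    name: str
    design: str
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample sizes must be >= 2")
        parse_design(self.design)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic dataset generator."""

    b6_params: ShapeParams
    donor_params: ShapeParams
    architecture: GeneticArchitecture
    groups: list  # of GroupSpec
    n_outline_points: int = 100
    rotation_range: float = 0.15  # rad, uniform nuisance rotation
    translation_range: float = 0.5
    scale_range: tuple = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        self.b6_params.validate()
        self.donor_params.validate()
        if self.n_outline_points < 8:
            raise ValueError("n_outline_points must be >= 8")

    def to_dict(self) -> dict:
        return {
            "b6_params": vars(self.b6_params),
            "donor_params": vars(self.donor_params),
            "architecture": {
                "loci": [
                    {
                        **{k: v for k, v in vars(l).items() if k != "effect"},
                        "effect": l.effect.tolist(),
                        "markers": [list(m) for m in l.markers],
                    }
                    for l in self.architecture.loci
                ],
                "epistasis": [vars(t) for t in self.architecture.epistasis],
                "residual_sd_shared": self.architecture.residual_sd_shared,
                "residual_sd_indep": (
                    None
                    if self.architecture.residual_sd_indep is None
                    else self.architecture.residual_sd_indep.tolist()
                ),
            },
            "groups": [vars(g) for g in self.groups],
            "n_outline_points": self.n_outline_points,
            "rotation_range": self.rotation_range,
            "translation_range": self.translation_range,
            "scale_range": list(self.scale_range),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_yaml(self, path=None) -> str:
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        import yaml

        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        elif "\n" in str(source):
            d = yaml.safe_load(str(source))
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        arch = d["architecture"]
        return cls(
            b6_params=ShapeParams(**d["b6_params"]),
            donor_params=ShapeParams(**d["donor_params"]),
            architecture=GeneticArchitecture(
                loci=[
                    Locus(
                        name=l["name"],
                        chromosome=l["chromosome"],
                        start_Mb=l["start_Mb"],
                        end_Mb=l["end_Mb"],
                        markers=[tuple(m) for m in l["markers"]],
                        effect=np.asarray(l["effect"]),
                        dominance=l["dominance"],
                        causal_marker=l["causal_marker"],
                    )
                    for l in arch["loci"]
                ],
                epistasis=[EpistasisTerm(**t) for t in arch["epistasis"]],
                residual_sd_shared=arch["residual_sd_shared"],
                residual_sd_indep=(
                    None
                    if arch["residual_sd_indep"] is None
                    else np.asarray(arch["residual_sd_indep"])
                ),
            ),
            groups=[GroupSpec(**g) for g in d["groups"]],
            n_outline_points=d["n_outline_points"],
            rotation_range=d["rotation_range"],
            translation_range=d["translation_range"],
            scale_range=tuple(d["scale_range"]),
            seed=d["seed"],
        )


@dataclass
class Dataset:
    """In-memory synthetic dataset: outlines + genotype + design tables."""

    outlines: list  # of Outline
    genotypes: GenotypeTable
    design: pd.DataFrame  # id, group
    config: SimulationConfig

    def group_outlines(self, group: str) -> list:
        ids = set(self.design.loc[self.design["group"] == group, "id"])
        return [o for o in self.outlines if o.specimen_id in ids]


def generate_dataset(config: SimulationConfig, outdir=None) -> Dataset:
    """Generate the full synthetic dataset described by ``config``.

    All randomness flows from one generator seeded with ``config.seed``,
    so identical configs reproduce identical data (and identical files
    byte-for-byte when ``outdir`` is given).  A manifest recording the
    seed and the config hash is written next to the files.
    """
    rng = np.random.default_rng(config.seed)
    arch = config.architecture
    outlines = []
    design_rows = []
    geno_frames = []
    counter = 0
    for spec in config.groups:
        table = simulate_genotypes(arch, spec.design, spec.n, rng)
        ids = [f"{spec.name}_{i + 1}" for i in range(spec.n)]
        table.genotypes.index = ids
        geno_frames.append(table.genotypes)
        for i, ind in enumerate(ids):
            locus_geno = {
                l.name: table.genotypes.loc[ind, l.causal_marker] for l in arch.loci
            }
            params = genotype_to_params(locus_geno, arch, config.b6_params)
            vec = params.geometry_vector()
            if arch.residual_sd_shared > 0:
                direction = arch.total_effect
                nrm = np.linalg.norm(direction)
                if nrm > 0:
                    vec = vec + (
                        arch.residual_sd_shared
                        * rng.standard_normal()
                        * direction
                        / nrm
                    )
            if arch.residual_sd_indep is not None:
                vec = vec + arch.residual_sd_indep * rng.standard_normal(len(vec))
            params = params.with_geometry(vec)
            outlines.append(
                make_outline(
                    params,
                    config.n_outline_points,
                    rng,
                    specimen_id=ind,
                    rotation_range=config.rotation_range,
                    translation_range=config.translation_range,
                    scale_range=config.scale_range,
                )
            )
            design_rows.append({"id": ind, "group": spec.name})
            counter += 1
    genotypes = GenotypeTable(pd.concat(geno_frames), _marker_map(arch))
    design = pd.DataFrame(design_rows)
    ds = Dataset(outlines, genotypes, design, config)
    if outdir is not None:
        _write_dataset(ds, outdir)
    return ds


def _write_dataset(ds: Dataset, outdir):
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tps(ds.outlines, out / "outlines.tps")
    geno = ds.genotypes.genotypes.copy()
    geno.insert(0, "group", ds.design.set_index("id")["group"])
    geno.rename_axis("id").reset_index().to_csv(out / "genotypes.csv", index=False)
    ds.genotypes.markers.rename_axis("marker").reset_index().to_csv(
        out / "markers.csv", index=False
    )
    ds.design.to_csv(out / "design.csv", index=False)
    manifest = {"seed": ds.config.seed, "config_hash": ds.config.config_hash(),
                "config": ds.config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Study-condition presets

#: recipient-strain pole: rectangular, notched, laterally depressed
B6_PARAMS = ShapeParams(
    length=2.0,
    caudal_width=1.0,
    rostral_ratio=1.0,
    notch_depth=0.16,
    depression_amp=0.10,
    corner_round=0.22,
    asymmetry_noise=0.01,
    landmark_jitter=0.01,
)

#: donor-segment carrier pole: trapezoidal, deeper notch, rounded rostrum
DONOR_PARAMS = ShapeParams(
    length=2.0,
    caudal_width=1.0,
    rostral_ratio=0.78,
    notch_depth=0.26,
    depression_amp=0.02,
    corner_round=0.38,
    asymmetry_noise=0.01,
    landmark_jitter=0.01,
)

#: fraction of the B6->donor difference carried by each causal segment
_EFFECT_SHARE = {"Chr1": 0.55, "Chr13": 0.0, "Chr18": 0.45}
#: shared residual shape noise along the effect axis, as a fraction of the
#: total genetic difference (sets per-locus detectability in the F2)
_RESIDUAL_SHARED_FRAC = 0.18
#: small independent per-parameter noise floor
_RESIDUAL_INDEP = np.array([0.02, 0.01, 0.01, 0.004, 0.005, 0.01])


def study_architecture(
    suppression: float = 0.8,
    dominance: dict | None = None,
    effect_share: dict | None = None,
) -> GeneticArchitecture:
    """Three-segment architecture mirroring the study's inference.

    Chr1-like and Chr18-like segments carry additive (codominant by
    default) effects toward the donor pole; the Chr13-like segment is
    null on its own but, when donor-homozygous, suppresses the Chr1-like
    effect by ``suppression``.
    """
    share = dict(_EFFECT_SHARE)
    if effect_share:
        share.update(effect_share)
    dom = {"Chr1": 0.0, "Chr13": 0.0, "Chr18": 0.0}
    if dominance:
        dom.update(dominance)
    delta = DONOR_PARAMS.geometry_vector() - B6_PARAMS.geometry_vector()
    loci = [
        Locus(
            name="Chr1",
            chromosome="1",
            start_Mb=87.599477,
            end_Mb=119.094898,
            markers=[
                ("D1Mit81", 87.599477),
                ("D1Mit84", 93.7),
                ("D1Mit306", 98.7),
                ("rs6259837", 119.094898),
            ],
            effect=share["Chr1"] * delta,
            dominance=dom["Chr1"],
            causal_marker="D1Mit306",
        ),
        Locus(
            name="Chr13",
            chromosome="13",
            start_Mb=93.838592,
            end_Mb=103.968912,
            markers=[("D13Mit106", 93.838592), ("D13Mit290", 103.968912)],
            effect=share["Chr13"] * delta,
            dominance=dom["Chr13"],
            causal_marker="D13Mit290",
        ),
        Locus(
            name="Chr18",
            chromosome="18",
            start_Mb=42.783975,
            end_Mb=56.096090,
            markers=[("D18Mit23", 42.783975), ("D18Mit123", 56.096090)],
            effect=share["Chr18"] * delta,
            dominance=dom["Chr18"],
            causal_marker="D18Mit123",
        ),
    ]
    scale = float(np.linalg.norm(delta))
    return GeneticArchitecture(
        loci=loci,
        epistasis=[EpistasisTerm("Chr13", "Chr1", suppression)],
        residual_sd_shared=_RESIDUAL_SHARED_FRAC * scale,
        residual_sd_indep=_RESIDUAL_INDEP.copy(),
    )


#: boundary markers of the three donor segments
SEGMENT_BOUNDARIES = {
    "Chr1": ("D1Mit81", "rs6259837"),
    "Chr13": ("D13Mit106", "D13Mit290"),
    "Chr18": ("D18Mit23", "D18Mit123"),
}


def f2_cross_config(seed: int = 0, **arch_kwargs) -> SimulationConfig:
    """F2-mapping study conditions: both parents, F1, and a 91-male F2.

    The F2 architecture is the one the intercross analysis supports: two
    additive codominant loci and a marginally null modifier (no
    suppression term), matching the observation that epistasis is
    invisible in the segregating cross and only emerges in bicongenic
    comparisons (see :func:`congenic_config`).
    """
    arch_kwargs.setdefault("suppression", 0.0)
    return SimulationConfig(
        b6_params=B6_PARAMS,
        donor_params=DONOR_PARAMS,
        architecture=study_architecture(**arch_kwargs),
        groups=[
            GroupSpec("B6", "inbred_B6", 20),
            GroupSpec("66H", "inbred_donor", 20),
            GroupSpec("F1", "F1", 18),
            GroupSpec("F2", "F2", 91),
        ],
        seed=seed,
    )


def congenic_config(seed: int = 0, **arch_kwargs) -> SimulationConfig:
    """Congenic/bicongenic study conditions (25–33 mice per strain).

    Carries the architecture the congenic comparisons support: donor
    allele recessive at the Chr1-like locus, dominant at the Chr18-like
    locus, and the Chr13-like segment suppressing the Chr1-like effect
    when donor-homozygous.
    """
    arch_kwargs.setdefault("suppression", 0.8)
    arch_kwargs.setdefault("dominance", {"Chr1": -1.0, "Chr18": 1.0})
    return SimulationConfig(
        b6_params=B6_PARAMS,
        donor_params=DONOR_PARAMS,
        architecture=study_architecture(**arch_kwargs),
        groups=[
            GroupSpec("B6", "inbred_B6", 28),
            GroupSpec("66H", "inbred_donor", 28),
            GroupSpec("Chr1", "congenic:Chr1", 28),
            GroupSpec("Chr13", "congenic:Chr13", 28),
            GroupSpec("Chr18", "congenic:Chr18", 28),
            GroupSpec("Chr1+13", "bicongenic:Chr1+Chr13", 28),
            GroupSpec("Chr13+18", "bicongenic:Chr13+Chr18", 28),
            GroupSpec("Chr1+18", "bicongenic:Chr1+Chr18", 28),
        ],
        seed=seed,
    )
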