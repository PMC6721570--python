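"""Synthetic study generator.

Emulates the study design end-to-end without patient data: textured
ellipsoidal lesions inside noise backgrounds (controllable via a
Gaussian-random-field correlation length), plus clinical, gene-mutation,
gene-expression and IHC protein tables whose survival times follow an
exponential proportional-hazards model with planted log-hazard effects and
independent censoring. Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .features import RADIOMIC_FEATURE_NAMES, extract_all
from .stats import SurvivalRecord
from .volume import ImageVolume, ROIMask, write_mask, write_volume

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_lesion",
    "generate_survival",
    "draw_survival_times",
    "generate_cohort",
    "default_planted_effects",
]

# First mutation genes get the names of recurrently mutated GBM genes; the
# six proteins are the routine IHC panel.
_NAMED_GENES = ["CIC", "PIK3R1", "FUBP1", "RYR2", "EGFR", "TP53", "PTEN", "NF1"]
PROTEIN_NAMES = ["Ki67", "EGFR", "PTEN", "CD44", "p53", "vimentin"]


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``planted_effects`` maps feature names (a radiomic feature, ``age``,
    ``kps``, ``mut_<gene>``, ``expr_<gene>`` or ``prot_<name>``) to
    log-hazard coefficients. Continuous features are z-scored across the
    cohort before entering the hazard; binary mutation indicators enter
    as 0/1, so their coefficient is a per-carrier log hazard ratio.
    """

    n_patients: int = 200
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_range_mm: tuple[float, float] = (8.0, 16.0)
    texture_scale_range_mm: tuple[float, float] = (1.0, 6.0)
    n_mutation_genes: int = 100
    n_expression_genes: int = 200
    n_proteins: int = 6
    planted_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 400.0  # per day
    censoring_rate: float = 0.1
    seed: int = 0
    with_images: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        for name in self.planted_effects:
            if not self._produces(name):
                raise ValueError(f"planted effect on unknown feature '{name}'")

    def _produces(self, name: str) -> bool:
        if name in ("age", "kps"):
            return True
        if name in RADIOMIC_FEATURE_NAMES:
            return self.with_images
        if name.startswith("mut_"):
            return name[4:] in self.mutation_gene_names()
        if name.startswith("expr_"):
            return name[5:] in self.expression_gene_names()
        if name.startswith("prot_"):
            return name[5:] in PROTEIN_NAMES[: self.n_proteins]
        return False

    def mutation_gene_names(self) -> list[str]:
        names = _NAMED_GENES[: self.n_mutation_genes]
        names += [f"g{i:03d}" for i in range(len(names), self.n_mutation_genes)]
        return names

    def expression_gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_expression_genes)]

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_planted_effects() -> dict[str, float]:
    """The standard planted-signal configuration: one strong protective
    radiomic effect (mirroring the protective association of sum-of-squares
    variance with survival) and one deleterious mutation."""
    return {
        "glcm_sum_of_squares_variance": -float(np.log(3.0)),
        "mut_CIC": float(np.log(2.5)),
    }


@dataclass
class SyntheticCohort:
    """In-memory synthetic study: feature blocks, survival records, and the
    per-patient lesion geometry parameters that generated them."""

    config: CohortConfig
    clinical: pd.DataFrame  # patient_id-indexed: age, sex, kps, therapy_type, os_days, event
    radiomics: pd.DataFrame | None
    mutations: pd.DataFrame
    expression: pd.DataFrame
    proteins: pd.DataFrame
    lesion_params: pd.DataFrame

    @property
    def records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(t, int(e))
            for t, e in zip(self.clinical["os_days"], self.clinical["event"])
        ]

    @property
    def patient_ids(self) -> list[str]:
        return self.clinical.index.tolist()


def _ellipsoid_mask(shape, spacing, radius_mm, axis_factors) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    semi = [radius_mm * f for f in axis_factors]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(
        ((g - c) * sp / a) ** 2
        for g, c, sp, a in zip(grids, center, spacing, semi)
    )
    return d2 <= 1.0


def generate_lesion(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius_mm: float,
    texture_scale_mm: float,
    seed: int,
    axis_factors: tuple[float, float, float] = (1.0, 0.9, 0.8),
) -> tuple[ImageVolume, ROIMask]:
    """One textured ellipsoidal lesion in a low-noise background.

    In-mask intensities are a Gaussian random field with the given
    correlation length, min-max rescaled into (0, 1]; the background is
    low-amplitude uniform noise. ``texture_scale_mm = inf`` yields a
    perfectly uniform lesion interior.
    """
    extent = [
        (s - 1) / 2.0 * sp for s, sp in zip(shape, spacing)
    ]
    if any(radius_mm * f > e - 2.0 for f, e in zip(axis_factors, extent)):
        raise ValueError(
            f"lesion radius {radius_mm} mm does not fit inside the field of view"
        )
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape, spacing, radius_mm, axis_factors)
    background = rng.uniform(0.0, 0.02, size=shape)
    vol = background
    if np.isinf(texture_scale_mm):
        vol[mask] = 0.55
    else:
        noise = rng.standard_normal(shape)
        sigma_vox = [texture_scale_mm / sp for sp in spacing]
        grf = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
        inside = grf[mask]
        lo, hi = inside.min(), inside.max()
        if hi == lo:
            vol[mask] = 0.55
        else:
            vol[mask] = 0.1 + 0.9 * (inside - lo) / (hi - lo)
    return (
        ImageVolume(vol, spacing),
        ROIMask(mask, spacing),
    )


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Rate c of an independent exponential censoring time such that the
    expected censored fraction, mean_i c/(c + h_i), equals ``target``."""
    if target <= 0:
        return 0.0

    def frac(c):
        return np.mean(c / (c + hazards)) - target

    hi = hazards.max() * target / (1 - target) * 10 + 1e-12
    while frac(hi) < 0:
        hi *= 10
    return float(optimize.brentq(frac, 1e-15, hi))


def draw_survival_times(
    hazards: np.ndarray, censoring_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times at the given per-patient hazards, with
    independent exponential censoring solved to hit the target censored
    fraction in expectation. Returns (observed times, event flags)."""
    hazards = np.asarray(hazards, dtype=float)
    t_event = rng.exponential(1.0 / hazards)
    if censoring_rate <= 0:
        times = np.maximum(t_event, 1e-9)
        return times, np.ones(len(hazards), dtype=int)
    c = _solve_censor_rate(hazards, censoring_rate)
    t_cens = rng.exponential(1.0 / c, size=len(hazards))
    times = np.maximum(np.minimum(t_event, t_cens), 1e-9)
    events = (t_event <= t_cens).astype(int)
    return times, events


def generate_survival(
    features: dict[str, float],
    effects: dict[str, float],
    baseline: float,
    censoring_rate: float,
    seed: int,
) -> SurvivalRecord:
    """Draw a single survival record at hazard
    ``baseline * exp(sum_i beta_i * z_i)`` with independent exponential
    censoring calibrated so the censoring probability equals
    ``censoring_rate`` for this hazard. Feature values are used as given
    (the caller standardizes them)."""
    missing = [k for k in effects if k not in features]
    if missing:
        raise ValueError(f"effect features absent: {missing}")
    lp = sum(beta * features[k] for k, beta in effects.items())
    h = baseline * np.exp(lp)
    rng = np.random.default_rng(seed)
    times, events = draw_survival_times(np.array([h]), censoring_rate, rng)
    return SurvivalRecord(float(times[0]), int(events[0]))


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)


def generate_cohort(
    config: CohortConfig, outdir: str | Path | None = None
) -> SyntheticCohort:
    """Generate the full synthetic study.

    Lesions are generated per patient (radius and texture correlation
    length drawn uniformly from the configured ranges), radiomic features
    extracted, omic and clinical tables drawn, and survival times sampled
    from the planted proportional-hazards model. With ``outdir`` the
    dataset is also written to disk (NIfTI volumes/masks, CSV tables, JSON
    manifest); files are bit-identical across reruns with the same config.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_patients + 1)
    rng = np.random.default_rng(child_seeds[-1])
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(n)]

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        (outdir / "volumes").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)

    radii = rng.uniform(*config.lesion_radius_range_mm, size=n)
    scales = rng.uniform(*config.texture_scale_range_mm, size=n)

    radiomics = None
    if config.with_images:
        rows = []
        for i in range(n):
            pseed = int(child_seeds[i].generate_state(1)[0] % (2**31))
            vol, mask = generate_lesion(
                config.volume_shape,
                config.voxel_spacing_mm,
                radii[i],
                scales[i],
                pseed,
            )
            rows.append(extract_all(vol, mask))
            if outdir is not None:
                write_volume(vol, outdir / "volumes" / f"{ids[i]}.nii.gz")
                write_mask(mask, outdir / "masks" / f"{ids[i]}.nii.gz")
        radiomics = pd.DataFrame(rows, index=ids)

    # clinical covariates: GBM-like demographics
    age = np.clip(rng.normal(62, 10, size=n), 18, 84).round(1)
    sex = rng.choice(["F", "M"], size=n)
    kps = rng.choice([40, 50, 60, 70, 80, 90, 100], size=n,
                     p=[0.03, 0.05, 0.10, 0.22, 0.30, 0.20, 0.10])
    therapy = rng.choice(["RT+TMZ", "RT", "none"], size=n, p=[0.6, 0.28, 0.12])

    gene_names = config.mutation_gene_names()
    mut_prev = rng.uniform(0.05, 0.4, size=len(gene_names))
    mutations = pd.DataFrame(
        (rng.random((n, len(gene_names))) < mut_prev).astype(int),
        index=ids, columns=[f"mut_{g}" for g in gene_names],
    )
    expr_names = config.expression_gene_names()
    expression = pd.DataFrame(
        rng.normal(0, 1, size=(n, len(expr_names))),
        index=ids, columns=[f"expr_{g}" for g in expr_names],
    )
    prot_names = PROTEIN_NAMES[: config.n_proteins]
    proteins = pd.DataFrame(
        rng.choice([0, 1, 2, 3], size=(n, len(prot_names)),
                   p=[0.2, 0.3, 0.3, 0.2]).astype(float),
        index=ids, columns=[f"prot_{p}" for p in prot_names],
    )

    pool = pd.concat(
        [df for df in (radiomics, mutations, expression, proteins) if df is not None],
        axis=1,
    )
    pool["age"] = age
    pool["kps"] = kps.astype(float)

    # planted hazard: z-score continuous features, leave 0/1 mutations as-is
    lp = np.zeros(n)
    for name, beta in config.planted_effects.items():
        col = pool[name].to_numpy(dtype=float)
        if name.startswith("mut_"):
            z = col
        else:
            z = _standardize(col)
        lp += beta * z
    hazards = config.baseline_hazard * np.exp(lp)
    times, events = draw_survival_times(hazards, config.censoring_rate, rng)

    clinical = pd.DataFrame(
        dict(age=age, sex=sex, kps=kps, therapy_type=therapy,
             os_days=np.round(times, 2), event=events),
        index=pd.Index(ids, name="patient_id"),
    )
    for df in (mutations, expression, proteins):
        df.index.name = "patient_id"
    if radiomics is not None:
        radiomics.index.name = "patient_id"
    lesion_params = pd.DataFrame(
        dict(radius_mm=radii, texture_scale_mm=scales),
        index=pd.Index(ids, name="patient_id"),
    )

    cohort = SyntheticCohort(
        config=config, clinical=clinical, radiomics=radiomics,
        mutations=mutations, expression=expression, proteins=proteins,
        lesion_params=lesion_params,
    )

    if outdir is not None:
        clinical.to_csv(outdir / "clinical.csv")
        mutations.to_csv(outdir / "mutations.csv")
        expression.to_csv(outdir / "expression.csv")
        proteins.to_csv(outdir / "proteins.csv")
        if radiomics is not None:
            radiomics.to_csv(outdir / "radiomics.csv")
        lesion_params.to_csv(outdir / "lesion_params.csv")
        manifest = dict(seed=config.seed, config=asdict(config),
                        config_digest=config.digest(), n_patients=n)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    return cohort
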