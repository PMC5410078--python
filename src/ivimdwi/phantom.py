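"""Digital DWI phantoms and synthetic subject cohorts.

The study this package models compared pancreatic ductal adenocarcinoma
(PDAC) against healthy pancreas on a nine-b-value DWI protocol; the raw
images are not public, so this module generates inputs with the same
statistical structure: two tissue classes whose IVIM parameters follow the
reported group means and standard deviations, simple ellipsoidal geometry,
and Rician magnitude noise.

Cohort sampling uses truncated Gaussians (truncation at the fit bounds)
because the reported spreads — e.g. a pseudo-diffusion coefficient of
6.39 +/- 5.55 x10^-3 mm^2/s — would otherwise produce negative
coefficients.  Tumor attributes (grade, stage, nodal status, location,
size) are sampled independently of the diffusion parameters, matching the
study's null findings by construction so the statistics layer's type-I
behavior is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import DWIStack, fit_monoexp
from .signal_models import BValueScheme, IVIMParams, biexp_signal, two_point_adc

__all__ = [
    "TissueSpec",
    "PhantomSpec",
    "CohortSpec",
    "CANCER_TISSUE",
    "HEALTHY_TISSUE",
    "build_phantom",
    "add_rician_noise",
    "sample_cohort_table",
    "simulate_cohort",
    "default_phantom_spec",
]

#: Fit-bound truncation limits used by the cohort sampler, matching the
#: fitting defaults (fraction, mm^2/s).
PARAM_BOUNDS = {"f": (0.0, 1.0), "adc_slow": (1e-5, 3e-3), "adc_fast": (3e-3, 5e-2)}


@dataclass(frozen=True)
class TissueSpec:
    """One tissue class: mean IVIM parameters, cohort spread, placement.

    ``geometry`` is an axis-aligned ellipsoid ``(center_mm, semi_axes_mm)``
    in the phantom's physical coordinates.
    """

    label: str
    params_mean: IVIMParams
    params_sd: dict = field(default_factory=dict)  # keys: f, adc_slow, adc_fast
    geometry: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        self.params_mean.validate()
        if any(v < 0 for v in self.params_sd.values()):
            raise ValueError("parameter spreads must be non-negative")


# Group means and SDs of the modeled populations (coefficients in mm^2/s;
# f is a fraction).  Cancer tissue diffuses and perfuses more slowly than
# healthy pancreas on every discriminating parameter.
CANCER_TISSUE = TissueSpec(
    label="cancer",
    params_mean=IVIMParams(s0=100.0, f=0.42, adc_slow=0.84e-3, adc_fast=6.39e-3),
    params_sd={"f": 0.15, "adc_slow": 0.32e-3, "adc_fast": 5.55e-3},
)
HEALTHY_TISSUE = TissueSpec(
    label="healthy",
    params_mean=IVIMParams(s0=100.0, f=0.39, adc_slow=0.92e-3, adc_fast=14.05e-3),
    params_sd={"f": 0.12, "adc_slow": 0.26e-3, "adc_fast": 8.31e-3},
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition scheme and noise level of one phantom.

    ``snr_b0`` is the ratio of tissue S0 to the Rician sigma; ``None`` (or
    ``inf``) means noiseless.  When tissues overlap, later-listed tissues
    win (an embedded tumor is listed after the surrounding pancreas).
    """

    shape: tuple[int, int, int] = (32, 32, 6)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    scheme: BValueScheme = field(default_factory=BValueScheme.study_scheme)
    tissues: tuple[TissueSpec, ...] = ()
    snr_b0: float | None = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_b0 is not None and not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive (or None for noiseless)")
        if any(s <= 0 for s in self.spacing) or any(n <= 0 for n in self.shape):
            raise ValueError("shape and spacing must be strictly positive")


def default_phantom_spec(
    tumor: bool = True,
    snr_b0: float | None = 40.0,
    seed: int = 0,
    tumor_params: IVIMParams | None = None,
    pancreas_params: IVIMParams | None = None,
) -> PhantomSpec:
    """An axial ellipsoidal "pancreas" with an optional embedded spherical
    "tumor", sized so the study's oval-ROI protocol (tumor ROI 55-308 mm^2)
    fits inside the lesion."""
    shape = (32, 32, 6)
    spacing = (2.0, 2.0, 5.0)
    center = tuple((n - 1) / 2 * s for n, s in zip(shape, spacing))
    pancreas = TissueSpec(
        label="pancreas",
        params_mean=pancreas_params or HEALTHY_TISSUE.params_mean,
        geometry=(center, (26.0, 18.0, 12.0)),
    )
    tissues = [pancreas]
    if tumor:
        tissues.append(
            TissueSpec(
                label="tumor",
                params_mean=tumor_params or CANCER_TISSUE.params_mean,
                geometry=(center, (8.0, 8.0, 8.0)),
            )
        )
    return PhantomSpec(
        shape=shape, spacing=spacing, tissues=tuple(tissues), snr_b0=snr_b0, seed=seed
    )


def _voxel_centers(shape, spacing):
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    return grids


def build_phantom(spec: PhantomSpec) -> tuple[DWIStack, np.ndarray]:
    """Rasterize a phantom and synthesize its DWI stack.

    Each voxel's noiseless signal is the biexponential forward model of
    its tissue's parameters at every b-value of the scheme; Rician noise
    is then applied if ``snr_b0`` is finite.  Returns the stack and an
    integer label volume (0 = background, tissue i+1 = ``tissues[i]``,
    later tissues overwrite earlier ones).  Deterministic given the seed.
    """
    if not spec.tissues:
        raise ValueError("phantom needs at least one tissue")
    labels = np.zeros(spec.shape, dtype=np.int16)
    xs, ys, zs = _voxel_centers(spec.shape, spec.spacing)
    for i, tissue in enumerate(spec.tissues, start=1):
        if tissue.geometry is None:
            raise ValueError(f"tissue {tissue.label!r} has no geometry")
        (cx, cy, cz), (ax, ay, az) = tissue.geometry
        inside = (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
        ) <= 1.0
        labels[inside] = i

    b = spec.scheme.array
    data = np.zeros(spec.shape + (len(b),), dtype=float)
    for i, tissue in enumerate(spec.tissues, start=1):
        mask = labels == i
        if not mask.any():
            continue
        data[mask, :] = biexp_signal(tissue.params_mean, b)

    stack = DWIStack(data=data, scheme=spec.scheme, spacing=spec.spacing)
    if spec.snr_b0 is not None and np.isfinite(spec.snr_b0):
        s0_ref = max(t.params_mean.s0 for t in spec.tissues)
        sigma = s0_ref / spec.snr_b0
        stack = add_rician_noise(stack, sigma, seed=spec.seed)
    return stack, labels


def add_rician_noise(stack: DWIStack, sigma: float, seed: int | None = None) -> DWIStack:
    """Corrupt a stack with Rician magnitude noise.

    Each sample S is replaced by ``sqrt((S + n1)^2 + n2^2)`` with n1, n2
    independent zero-mean Gaussians of scale ``sigma`` — the magnitude of a
    complex signal whose two channels each carry Gaussian noise.
    ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DWIStack(
            data=stack.data.copy(), scheme=stack.scheme,
            spacing=stack.spacing, affine=stack.affine,
        )
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, stack.data.shape)
    n2 = rng.normal(0.0, sigma, stack.data.shape)
    noisy = np.sqrt((stack.data + n1) ** 2 + n2**2)
    return DWIStack(
        data=noisy, scheme=stack.scheme, spacing=stack.spacing, affine=stack.affine
    )


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    Defaults reproduce the modeled study population: 51 PDAC patients and
    57 healthy controls; 14/51 tumors poorly differentiated, 30/51 in the
    pancreatic head, 38/51 stage T3/T4, 29/51 with metastatic
    peri-pancreatic nodes; tumor size 35 +/- 12 mm (range 15-90 mm).
    """

    n_cancer: int = 51
    n_healthy: int = 57
    p_poor_grade: float = 14 / 51
    p_head: float = 30 / 51
    p_t34: float = 38 / 51
    p_nodal: float = 29 / 51
    size_mean_mm: float = 35.0
    size_sd_mm: float = 12.0
    size_range_mm: tuple[float, float] = (15.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer <= 0 or self.n_healthy <= 0:
            raise ValueError("group sizes must be positive")
        for p in (self.p_poor_grade, self.p_head, self.p_t34, self.p_nodal):
            if not 0.0 <= p <= 1.0:
                raise ValueError("attribute frequencies must lie in [0, 1]")


def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_group(tissue: TissueSpec, n: int, rng) -> pd.DataFrame:
    cols = {}
    for name in ("f", "adc_slow", "adc_fast"):
        mean = getattr(tissue.params_mean, name)
        sd = tissue.params_sd.get(name, 0.0)
        lo, hi = PARAM_BOUNDS[name]
        cols[name] = _truncnorm(mean, sd, lo, hi, n, rng)
    # keep compartments ordered; resample collisions against the joint rule
    bad = cols["adc_slow"] >= cols["adc_fast"]
    while bad.any():  # bounds make this rare (slow <= 3e-3 <= fast)
        cols["adc_fast"][bad] = _truncnorm(
            tissue.params_mean.adc_fast, tissue.params_sd.get("adc_fast", 0.0),
            *PARAM_BOUNDS["adc_fast"], int(bad.sum()), rng,
        )
        bad = cols["adc_slow"] >= cols["adc_fast"]
    return pd.DataFrame(cols)


def _derived_truth(df: pd.DataFrame, scheme: BValueScheme, s0: float) -> pd.DataFrame:
    """Noiseless-signal derived parameters: per-b two-point ADCs and the
    monoexponential ADC_total the fitter would report on clean data."""
    b = scheme.array
    out = {}
    sig = np.empty((len(df), len(b)))
    for i, row in enumerate(df.itertuples(index=False)):
        p = IVIMParams(s0=s0, f=row.f, adc_slow=row.adc_slow, adc_fast=row.adc_fast)
        sig[i] = biexp_signal(p, b)
    for j, bv in enumerate(b[1:], start=1):
        out[f"adc_{int(bv)}"] = two_point_adc(sig[:, 0], sig[:, j], bv)
    out["adc_total"] = [
        fit_monoexp(sig[i], scheme).adc_total for i in range(len(df))
    ]
    return pd.DataFrame(out)


def sample_cohort_table(
    spec: CohortSpec,
    scheme: BValueScheme | None = None,
    seed: int | None = None,
    derived: bool = True,
    s0: float = 100.0,
) -> pd.DataFrame:
    """Draw the per-subject true-parameter table (no images).

    Cancer and healthy subjects get IVIM parameters from their group's
    truncated Gaussian; cancer subjects additionally get grade, location,
    T stage, nodal status and size, drawn independently of the parameters.
    With ``derived=True`` the per-b two-point ADCs and ADC_total implied by
    the noiseless signal are appended, so the table can feed the statistics
    layer directly.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    scheme = scheme or BValueScheme.study_scheme()

    cancer = _sample_group(CANCER_TISSUE, spec.n_cancer, rng)
    cancer.insert(0, "group", "cancer")
    cancer["grade"] = np.where(
        rng.random(spec.n_cancer) < spec.p_poor_grade, "poor", "moderate"
    )
    cancer["location"] = np.where(
        rng.random(spec.n_cancer) < spec.p_head, "head", "elsewhere"
    )
    cancer["t_stage"] = np.where(rng.random(spec.n_cancer) < spec.p_t34, "T3/T4", "T1/T2")
    cancer["nodal"] = np.where(
        rng.random(spec.n_cancer) < spec.p_nodal, "present", "absent"
    )
    cancer["size_mm"] = _truncnorm(
        spec.size_mean_mm, spec.size_sd_mm, *spec.size_range_mm, spec.n_cancer, rng
    )

    healthy = _sample_group(HEALTHY_TISSUE, spec.n_healthy, rng)
    healthy.insert(0, "group", "healthy")
    for col in ("grade", "location", "t_stage", "nodal"):
        healthy[col] = pd.NA
    healthy["size_mm"] = np.nan

    table = pd.concat([cancer, healthy], ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])
    if derived:
        table = pd.concat([table, _derived_truth(table, scheme, s0)], axis=1)
    return table


def simulate_cohort(
    spec: CohortSpec,
    template: PhantomSpec | None = None,
    seed: int | None = None,
):
    """Sample a cohort table and (optionally) one phantom stack per subject.

    With a ``template``, each subject gets a phantom built from the
    template geometry with the subject's true parameters substituted:
    cancer subjects carry a tumor with their own parameters inside a
    pancreas at the healthy means; healthy subjects carry a tumor-free
    pancreas at their own parameters.  Returns ``(table, stacks)`` where
    ``stacks`` maps subject_id to (DWIStack, label volume); without a
    template, ``stacks`` is empty.
    """
    base_seed = spec.seed if seed is None else seed
    table = sample_cohort_table(spec, seed=base_seed)
    stacks: dict[str, tuple[DWIStack, np.ndarray]] = {}
    if template is None:
        return table, stacks
    ss = np.random.SeedSequence(base_seed)
    child_seeds = ss.spawn(len(table))
    for i, row in enumerate(table.itertuples(index=False)):
        params = IVIMParams(
            s0=100.0, f=row.f, adc_slow=row.adc_slow, adc_fast=row.adc_fast
        )
        sub_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        if row.group == "cancer":
            sub_spec = default_phantom_spec(
                tumor=True, snr_b0=template.snr_b0, seed=sub_seed, tumor_params=params
            )
        else:
            sub_spec = default_phantom_spec(
                tumor=False, snr_b0=template.snr_b0, seed=sub_seed,
                pancreas_params=params,
            )
        stacks[row.subject_id] = build_phantom(sub_spec)
    return table, stacks
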