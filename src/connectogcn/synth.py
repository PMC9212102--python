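"""Seeded synthetic multisite cohort generator.

Emulates the statistical structure a multisite case-control resting-state
fMRI study presents to the downstream analysis:

* regional BOLD-like time series drawn from a multivariate normal with a
  block-structured correlation matrix (within-network blocks ~0.4 on a 0.1
  background), so per-subject KNN graphs have non-trivial neighborhoods;
* a patient group whose correlations among a designated set of "signal"
  regions are reduced (hypoconnectivity) by ``effect_size`` scaled by a
  per-subject effect magnitude, giving between-subject severity variation;
* per-site additive/multiplicative edge-level batch effects, injected on
  Fisher-z edges (where ComBat operates);
* symptom scores whose negative dimension is coupled to the per-subject
  effect magnitude, so symptom-topology correlations are recoverable.

The default site layout mirrors a 6-site cohort of 505 patients and 907
controls in which the second site contributed controls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Default per-site (n_patients, n_controls): 6 sites, site 2 control-only.
DEFAULT_SITE_SIZES: tuple[tuple[int, int], ...] = (
    (301, 217),
    (0, 340),
    (49, 63),
    (32, 83),
    (67, 72),
    (56, 132),
)

# Bilateral amygdala, caudate, putamen, pallidum, thalamus under an AAL-like
# ordering; purely a labeling convenience.
DEFAULT_SIGNAL_NODES: tuple[int, ...] = (40, 41, 70, 71, 72, 73, 74, 75, 76, 77)


class ConfigurationError(ValueError):
    """A SynthConfig field is invalid."""


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    ``effect_size`` is the mean reduction of the pairwise correlation among
    ``signal_nodes`` in patients relative to controls; each patient draws an
    effect magnitude ~ N(1, magnitude_sd^2) truncated to
    [1 - 2.8*magnitude_sd, 1 + 2.8*magnitude_sd] (symmetric, so the mean
    reduction stays at ``effect_size``). ``site_shift`` / ``site_scale`` set
    the spread of per-site additive offsets and multiplicative factors
    applied to Fisher-z edges. ``symptom_coupling`` is the target Pearson
    correlation between a patient's effect magnitude and their
    negative-symptom score.
    """

    n_regions: int = 90
    n_sites: int = 6
    site_sizes: tuple[tuple[int, int], ...] = DEFAULT_SITE_SIZES
    n_timepoints: int = 200
    signal_nodes: tuple[int, ...] = DEFAULT_SIGNAL_NODES
    effect_size: float = 0.3
    magnitude_sd: float = 0.25
    site_shift: float = 0.3
    site_scale: float = 0.2
    symptom_coupling: float = 0.6
    block_size: int = 15
    within_block_r: float = 0.4
    background_r: float = 0.1
    signal_within_r: float = 0.7
    scale_min: float = 7.0
    scale_max: float = 49.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ConfigurationError("n_regions: need at least 2 regions")
        if len(self.site_sizes) != self.n_sites:
            raise ConfigurationError(
                f"site_sizes: {len(self.site_sizes)} entries for n_sites={self.n_sites}"
            )
        for t, (p, c) in enumerate(self.site_sizes):
            if p < 0 or c < 0 or p + c < 2:
                raise ConfigurationError(
                    f"site_sizes: site {t + 1} must have >= 2 subjects"
                )
        n_pat = sum(p for p, _ in self.site_sizes)
        if n_pat > 0:
            control_only = sum(1 for p, _ in self.site_sizes if p == 0)
            if control_only != 1:
                raise ConfigurationError(
                    "site_sizes: a mixed cohort must have exactly one "
                    f"control-only site (found {control_only})"
                )
        nodes = tuple(sorted(self.signal_nodes))
        if any(i < 0 or i >= self.n_regions for i in nodes):
            raise ConfigurationError("signal_nodes: indices must lie in [0, n_regions)")
        if len(set(nodes)) != len(nodes):
            raise ConfigurationError("signal_nodes: duplicate indices")
        self.signal_nodes = nodes
        if not 0 <= self.effect_size < 1:
            raise ConfigurationError("effect_size: must be in [0, 1)")
        if not -1 <= self.symptom_coupling <= 1:
            raise ConfigurationError("symptom_coupling: must be in [-1, 1]")
        if self.site_shift < 0 or self.site_scale < 0:
            raise ConfigurationError("site_shift/site_scale: must be nonnegative")
        if self.n_timepoints < 4:
            raise ConfigurationError("n_timepoints: need at least 4 timepoints")
        if self.scale_max <= self.scale_min:
            raise ConfigurationError("scale_max must exceed scale_min")

    @property
    def region_labels(self) -> list[str]:
        return [f"region_{i:03d}" for i in range(self.n_regions)]


@dataclass
class SubjectRecord:
    """One participant: site, diagnosis, covariates, symptom scores.

    ``effect_magnitude`` is simulation ground truth (None for controls);
    symptom scores are None for controls, mimicking scales administered to
    patients only.
    """

    subject_id: str
    site_id: str
    diagnosis: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    symptom_positive: float | None = None
    symptom_negative: float | None = None
    scale_min: float = 7.0
    scale_max: float = 49.0
    effect_magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("patient", "control"):
            raise ValueError(f"diagnosis must be patient|control, got {self.diagnosis}")
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        for score in (self.symptom_positive, self.symptom_negative):
            if score is not None and not (
                self.scale_min <= score <= self.scale_max
            ):
                raise ValueError(
                    f"symptom score {score} outside scale "
                    f"[{self.scale_min}, {self.scale_max}]"
                )


@dataclass
class RoiTimeSeries:
    """BOLD-like values, shape (n_timepoints, n_regions)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        if np.any(v.std(axis=0) == 0):
            raise ValueError("time series has a constant-valued region")
        self.values = v


@dataclass
class SiteEffectParams:
    """Per-site edge-level batch parameters: y -> gamma + delta * y."""

    site_ids: list[str]
    gamma: np.ndarray  # (n_sites, n_edges) additive offsets
    delta: np.ndarray  # (n_sites, n_edges) positive multiplicative factors


def base_correlation(config: SynthConfig) -> np.ndarray:
    """Control-group (population) correlation matrix implied by the factors.

    The time-series model is a latent-factor construction, so the matrix is
    positive definite by design: every region loads sqrt(background_r) on a
    global factor; non-signal regions load on their block factor to reach
    ``within_block_r`` within blocks; signal regions instead share a signal
    factor reaching ``signal_within_r`` among themselves.
    """
    a = config.n_regions
    sig = np.zeros(a, dtype=bool)
    sig[list(config.signal_nodes)] = True
    r = np.full((a, a), config.background_r)
    for start in range(0, a, config.block_size):
        stop = min(start + config.block_size, a)
        blk = np.zeros(a, dtype=bool)
        blk[start:stop] = True
        both = blk & ~sig
        r[np.ix_(both, both)] = config.within_block_r
    if sig.sum() >= 2:
        r[np.ix_(sig, sig)] = config.signal_within_r
    np.fill_diagonal(r, 1.0)
    return r


def patient_correlation(config: SynthConfig, magnitude: float) -> np.ndarray:
    """Patient correlation: signal-pair correlations reduced by effect*magnitude."""
    r = base_correlation(config)
    sig = np.array(config.signal_nodes, dtype=int)
    if sig.size >= 2:
        block = r[np.ix_(sig, sig)] - config.effect_size * magnitude
        r[np.ix_(sig, sig)] = block
        np.fill_diagonal(r, 1.0)
    return r


def _magnitude_bounds(config: SynthConfig) -> tuple[float, float]:
    lo = max(0.0, 1.0 - 2.8 * config.magnitude_sd)
    hi = 1.0 + 2.8 * config.magnitude_sd
    if config.effect_size > 0:
        # keep the signal-factor loading (hence all correlations) valid
        cap = (config.signal_within_r - config.background_r) / config.effect_size
        if cap < lo:
            raise ConfigurationError(
                "effect_size: too large for the signal-factor loading "
                f"(signal_within_r - background_r = "
                f"{config.signal_within_r - config.background_r:g})"
            )
        hi = min(hi, cap)
    return lo, hi


def _sample_series(
    rng: np.random.Generator, config: SynthConfig, signal_loading_sq: float
) -> np.ndarray:
    """One subject's series from the factor model.

    x_i = sqrt(bg)*g + sqrt(within-bg)*f_block(i) + sqrt(1-within)*eps_i for
    non-signal regions; signal regions replace the block term with
    sqrt(l2)*s + sqrt(1-bg-l2)*eps_i where l2 = signal_loading_sq.
    """
    a, T = config.n_regions, config.n_timepoints
    n_blocks = -(-a // config.block_size)
    g = rng.standard_normal((T, 1))
    f = rng.standard_normal((T, n_blocks))
    s = rng.standard_normal((T, 1))
    eps = rng.standard_normal((T, a))

    bg = config.background_r
    wb = config.within_block_r
    block_of = np.arange(a) // config.block_size
    x = np.sqrt(bg) * g + np.sqrt(wb - bg) * f[:, block_of] + np.sqrt(1 - wb) * eps
    sig = np.array(config.signal_nodes, dtype=int)
    if sig.size:
        l2 = signal_loading_sq
        x[:, sig] = (
            np.sqrt(bg) * g
            + np.sqrt(l2) * s
            + np.sqrt(1 - bg - l2) * eps[:, sig]
        )
    return x


def generate_cohort(
    config: SynthConfig,
) -> tuple[list[SubjectRecord], list[RoiTimeSeries]]:
    """Generate subject records and ROI time series for the whole cohort.

    Deterministic given ``config.seed``. Patients carry a per-subject effect
    magnitude (stored on the record) that scales their hypoconnectivity and
    drives the negative-symptom score via :func:`generate_symptoms`.
    """
    rng = np.random.default_rng([11, config.seed])
    control_l2 = config.signal_within_r - config.background_r
    lo, hi = _magnitude_bounds(config)

    records: list[SubjectRecord] = []
    series: list[RoiTimeSeries] = []
    for t, (n_pat, n_con) in enumerate(config.site_sizes):
        site_id = f"site{t + 1}"
        for group, n in (("patient", n_pat), ("control", n_con)):
            for i in range(n):
                sid = f"{site_id}_{group[:3]}_{i:04d}"
                age = float(np.clip(rng.normal(31.0, 9.0), 18.0, 65.0))
                sex = "M" if rng.random() < 0.5 else "F"
                if group == "patient":
                    mag = float(np.clip(rng.normal(1.0, config.magnitude_sd), lo, hi))
                    l2 = control_l2 - config.effect_size * mag
                else:
                    mag = None
                    l2 = control_l2
                ts = _sample_series(rng, config, l2)
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        site_id=site_id,
                        diagnosis=group,
                        age=age,
                        sex=sex,
                        scale_min=config.scale_min,
                        scale_max=config.scale_max,
                        effect_magnitude=mag,
                    )
                )
                series.append(RoiTimeSeries(subject_id=sid, values=ts))

    magnitudes = np.array(
        [r.effect_magnitude for r in records if r.diagnosis == "patient"]
    )
    generate_symptoms(records, magnitudes, config)
    return records, series


def generate_symptoms(
    records: list[SubjectRecord],
    effect_magnitudes: np.ndarray,
    config: SynthConfig,
) -> list[SubjectRecord]:
    """Fill patients' symptom scores in place (controls stay absent).

    The negative-symptom score is built from the standardized effect
    magnitude mixed with noise at ``symptom_coupling``, mapped onto the
    declared scale (center 17, spread 7 — PANSS-negative-like), then clipped
    to the scale bounds. The positive score is independent noise
    (center 20, spread 9).
    """
    if not -1 <= config.symptom_coupling <= 1:
        raise ConfigurationError("symptom_coupling: must be in [-1, 1]")
    patients = [r for r in records if r.diagnosis == "patient"]
    mags = np.asarray(effect_magnitudes, dtype=float)
    if mags.size != len(patients):
        raise ValueError(
            f"got {mags.size} magnitudes for {len(patients)} patients"
        )
    if not patients:
        return records
    rng = np.random.default_rng([13, config.seed])
    sd = mags.std()
    std_m = (mags - mags.mean()) / sd if sd > 0 else np.zeros_like(mags)
    c = config.symptom_coupling
    latent = c * std_m + np.sqrt(1.0 - c * c) * rng.standard_normal(mags.size)
    neg = np.clip(17.0 + 7.0 * latent, config.scale_min, config.scale_max)
    pos = np.clip(
        20.0 + 9.0 * rng.standard_normal(mags.size),
        config.scale_min,
        config.scale_max,
    )
    for rec, sn, sp in zip(patients, neg, pos):
        rec.symptom_negative = float(sn)
        rec.symptom_positive = float(sp)
    return records


def draw_site_effects(
    config: SynthConfig, site_ids: list[str], n_edges: int
) -> SiteEffectParams:
    """Draw per-site x edge batch parameters once from the config seed.

    gamma ~ N(0, site_shift^2); delta lognormal with mean exactly 1 and
    standard deviation ``site_scale`` (so delta > 0 always). Draws are
    independent of diagnosis by construction.
    """
    uniq = sorted(set(site_ids))
    rng = np.random.default_rng([17, config.seed])
    gamma = rng.normal(0.0, config.site_shift, size=(len(uniq), n_edges))
    if config.site_scale > 0:
        s2 = np.log1p(config.site_scale**2)
        delta = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=gamma.shape)
    else:
        delta = np.ones_like(gamma)
    return SiteEffectParams(site_ids=uniq, gamma=gamma, delta=delta)


def inject_site_effects(
    z_edges: np.ndarray,
    site_ids: list[str],
    config: SynthConfig,
    params: SiteEffectParams | None = None,
) -> tuple[np.ndarray, SiteEffectParams]:
    """Apply y -> gamma_site + delta_site * y per edge; inputs unmodified.

    Returns the new matrix together with the drawn parameters so callers can
    audit the injected effects.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    if z_edges.ndim != 2 or z_edges.shape[0] != len(site_ids):
        raise ValueError(
            f"edge matrix has {z_edges.shape[0]} rows for {len(site_ids)} site ids"
        )
    if params is None:
        params = draw_site_effects(config, list(site_ids), z_edges.shape[1])
    index = {s: i for i, s in enumerate(params.site_ids)}
    out = np.empty_like(z_edges)
    for row, site in enumerate(site_ids):
        i = index[site]
        out[row] = params.gamma[i] + params.delta[i] * z_edges[row]
    return out, params


# ---------------------------------------------------------------------------
# Plain-text artifact writers


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "site_id": [r.site_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "symptom_positive": [r.symptom_positive for r in records],
            "symptom_negative": [r.symptom_negative for r in records],
            "scale_min": [r.scale_min for r in records],
            "scale_max": [r.scale_max for r in records],
        }
    )


def write_subject_table(records: list[SubjectRecord], path) -> None:
    subjects_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_subject_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                site_id=str(row.site_id),
                diagnosis=str(row.diagnosis),
                age=float(row.age),
                sex=str(row.sex),
                symptom_positive=None
                if pd.isna(row.symptom_positive)
                else float(row.symptom_positive),
                symptom_negative=None
                if pd.isna(row.symptom_negative)
                else float(row.symptom_negative),
                scale_min=float(row.scale_min),
                scale_max=float(row.scale_max),
            )
        )
    return records


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    """Per-subject TSV: rows = timepoints, columns = regions."""
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")


def read_timeseries(path, subject_id: str = "") -> RoiTimeSeries:
    return RoiTimeSeries(subject_id=subject_id, values=np.loadtxt(path, delimiter="\t"))


def write_atlas(region_labels: list[str], path) -> None:
    """Two-column TSV: region index, region name."""
    with open(path, "w") as fh:
        for i, name in enumerate(region_labels):
            fh.write(f"{i}\t{name}\n")
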