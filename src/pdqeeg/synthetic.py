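"""Synthetic study data with recoverable ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: EEG recordings with known per-band power fractions, blink artifacts
and bad channels; two-visit cognitive test tables whose follow-up change is
a planted linear function of baseline qEEG theta power, executive function
and working memory; and a normative table for z-scoring.

EEG model
---------
A recording is a linear mixture of a small number of shared band-limited
sources (random-phase Fourier synthesis, spectrum strictly confined to each
band) plus a little per-channel noise carrying the same band profile.  The
mixture weights are scaled so that every channel's variance splits across
the five bands exactly in the requested proportions, which makes the
relative band power an analytic target.  The low-rank source structure is
deliberate: scalp EEG is a volume-conducted mixture of cortical sources,
and this is precisely the generative model that ICA-based artifact removal
assumes.

Blink artifacts are 300 ms raised-cosine transients at 8x the background
standard deviation, confined to the designated frontal channels (the first
10% of the montage).  Bad channels are either flat or grossly high-variance.

Cohort model
------------
The planted outcome is

    t_i = intercept + b_theta * GRMPtheta_i + b_exec * Exec_i + b_wm * WM_i + eps_i

and follow-up test scores are shifted so that the paired difference in the
overall cognitive score equals ``t_i`` exactly.  Because the observed change
index divides by the cohort SD of the paired differences, the default
``noise_sd`` is chosen so that ``t`` has approximately unit variance under
the default coefficients — the planted betas are then recovered on their own
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import BATTERY, TESTS, tests_in_domain
from .recording import EEGRecording
from .spectral import DEFAULT_BANDS

# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

#: cohort-typical band fractions (baseline medians of the five bands,
#: renormalised to sum to one)
DEFAULT_FRACTIONS = {
    "delta": 0.242,
    "theta": 0.198,
    "alpha1": 0.198,
    "alpha2": 0.143,
    "beta": 0.219,
}


@dataclass
class EEGGenSpec:
    n_channels: int = 24               # scalp channels (reference added on top)
    sampling_rate: float = 200.0       # Hz
    duration: float = 180.0            # s
    band_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    background_exponent: float = 0.0   # 1/f^a broadband floor; 0 disables
    background_fraction: float = 0.0   # variance share of the 1/f floor
    blink_rate: float = 0.0            # events per minute
    n_bad_channels: int = 0
    seed: int = 0
    # secondary knobs of the source-mixture model
    k_sources: int = 2                 # shared sources per band
    noise_frac: float = 0.05           # per-channel noise share of variance
    n_occipital: int = 4
    rms_uv: float = 40.0               # per-channel RMS amplitude, microvolts

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        total = sum(self.band_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band fractions must sum to 1 (got {total})")
        if any(not 0 <= v <= 1 for v in self.band_fractions.values()):
            raise ValueError("band fractions must lie in [0, 1]")
        n_samp = self.duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer sample count")
        if self.n_bad_channels >= self.n_channels:
            raise ValueError("n_bad_channels must be smaller than n_channels")
        unknown = set(self.band_fractions) - set(DEFAULT_BANDS.bands)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise with flat spectrum on [lo, hi) and zero outside."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = ((freqs >= lo) & (freqs < hi)).astype(float)
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phases, n)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"band [{lo}, {hi}) Hz is empty at fs={fs}")
    return x / sd


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Roughly uniform unit-sphere electrode layout (south of the vertex)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (i + 0.5) / n * 1.6          # upper cap of the sphere
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def blink_template(sfreq: float, width_s: float = 0.3) -> np.ndarray:
    """Raised-cosine blink transient of ``width_s`` seconds."""
    n = int(round(width_s * sfreq))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def generate_eeg(spec: EEGGenSpec) -> EEGRecording:
    """Synthesize one recording; identical spec (incl. seed) gives identical samples."""
    n = int(round(spec.duration * spec.sampling_rate))
    n_ch = spec.n_channels
    fs = spec.sampling_rate
    # independent streams so that e.g. turning blinks off leaves the
    # background bit-identical (twin recordings share a seed)
    rng_bg = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    rng_blink = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    rng_bad = np.random.default_rng(np.random.SeedSequence((spec.seed, 3)))

    data = np.zeros((n_ch, n))
    signal_share = 1.0 - spec.background_fraction
    for band, (lo, hi) in DEFAULT_BANDS:
        frac = spec.band_fractions.get(band, 0.0)
        if frac <= 0:
            continue
        shared = np.stack([_band_noise(rng_bg, n, fs, lo, hi) for _ in range(spec.k_sources)])
        mix = rng_bg.standard_normal((n_ch, spec.k_sources))
        mix *= np.sqrt(frac * signal_share * (1 - spec.noise_frac)) / np.linalg.norm(
            mix, axis=1, keepdims=True
        )
        data += mix @ shared
        own = np.stack([_band_noise(rng_bg, n, fs, lo, hi) for _ in range(n_ch)])
        data += np.sqrt(frac * signal_share * spec.noise_frac) * own
    if spec.background_fraction > 0 and spec.background_exponent > 0:
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        shape = np.zeros_like(freqs)
        nz = freqs > 0
        shape[nz] = freqs[nz] ** (-spec.background_exponent / 2.0)
        for c in range(n_ch):
            ph = rng_bg.standard_normal(freqs.size) + 1j * rng_bg.standard_normal(freqs.size)
            bg = np.fft.irfft(shape * ph, n)
            data[c] += np.sqrt(spec.background_fraction) * bg / bg.std()

    data *= spec.rms_uv

    labels = [f"E{i + 1:02d}" for i in range(n_ch)]
    roles = ["active"] * n_ch
    for i in range(max(0, n_ch - spec.n_occipital), n_ch):
        roles[i] = "occipital"

    # blink artifacts on the designated frontal channels
    n_frontal = max(1, round(0.1 * n_ch))
    if spec.blink_rate > 0:
        tmpl = blink_template(fs)
        amp = 8.0 * np.median(data.std(axis=1))
        n_events = rng_blink.poisson(spec.blink_rate * spec.duration / 60.0)
        if n_events:
            starts = rng_blink.integers(0, n - tmpl.size, n_events)
            for t0 in starts:
                data[:n_frontal, t0:t0 + tmpl.size] += amp * tmpl

    # bad channels: flat or grossly high-variance, never frontal/occipital
    if spec.n_bad_channels:
        candidates = np.arange(n_frontal, n_ch - spec.n_occipital)
        if candidates.size < spec.n_bad_channels:
            raise ValueError("too many bad channels for this montage")
        bad_idx = rng_bad.choice(candidates, size=spec.n_bad_channels, replace=False)
        for j, c in enumerate(sorted(bad_idx)):
            if j % 2 == 0:
                data[c] = 0.0
            else:
                data[c] *= 10.0

    # append the flat recording reference at the vertex
    data = np.vstack([data, np.zeros((1, n))])
    positions = np.vstack([_fibonacci_sphere(n_ch), [0.0, 0.0, 1.0]])
    labels.append("Cz")
    roles.append("reference")
    return EEGRecording(
        data=data, sfreq=fs, labels=labels, positions=positions, roles=roles,
        reference_label="Cz",
    )


# ---------------------------------------------------------------------------
# Spectral-feature sampling (for cohorts too large to simulate EEG per head)
# ---------------------------------------------------------------------------

def sample_spectral_features(
    n: int,
    seed: int | np.random.Generator = 0,
    sigma: float = 0.35,
) -> pd.DataFrame:
    """Draw per-subject GRMP fractions and occipital median frequency.

    Band fractions follow a logistic-normal law centred on the cohort-typical
    medians (``sigma`` is the log-scale spread; 0.35 reproduces the published
    baseline ranges).  The median frequency is truncated normal around
    8.7 Hz.  Used by cohort-level studies where simulating one EEG per
    subject would add nothing but runtime.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(DEFAULT_FRACTIONS)
    med = np.array([DEFAULT_FRACTIONS[b] for b in names])
    g = np.log(med) + sigma * rng.standard_normal((n, len(names)))
    f = np.exp(g)
    f /= f.sum(axis=1, keepdims=True)
    out = pd.DataFrame(f, columns=[f"grmp_{b}" for b in names])
    out["occipital_mf_hz"] = np.clip(rng.normal(8.7, 0.6, n), 7.0, 10.0)
    out.index = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="subject_id")
    return out


# ---------------------------------------------------------------------------
# Normative table
# ---------------------------------------------------------------------------

def generate_norms(test_list: list[str] | tuple[str, ...] = TESTS, seed: int = 0) -> pd.DataFrame:
    """Normative mean/SD and direction flag per test (synthetic stand-in).

    Emulates a healthy-control normative database; means and SDs are
    plausible values for each instrument with a small seeded jitter.
    """
    if not test_list:
        raise ValueError("test list is empty")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 10)))
    rows = []
    for t in test_list:
        if t not in BATTERY:
            raise KeyError(f"unknown test {t!r}")
        _domain, hib, mean, sd = BATTERY[t]
        jitter = 1.0 + 0.03 * rng.standard_normal()
        rows.append({"test": t, "mean": mean * jitter, "sd": sd, "higher_is_better": hib})
    return pd.DataFrame(rows).set_index("test")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: baseline covariate laws, matched to the published cohort ranges
DEFAULT_COVARIATES = {
    "age": ("truncnorm", 67.0, 9.0, 31.0, 84.0),
    "sex_male": ("bernoulli", 25.0 / 37.0),
    "education_years": ("truncnorm", 14.0, 3.0, 9.0, 20.0),
    "disease_duration_years": ("trunclognorm", 8.0, 0.5, 1.0, 20.0),
    "observation_months": ("truncnorm", 37.0, 3.0, 30.0, 44.0),
    "ledd_mg": ("trunclognorm", 691.0, 0.5, 150.0, 2129.0),
    "updrs3": ("truncnorm", 14.0, 8.0, 0.0, 50.0),
    "bdi2": ("truncnorm", 6.0, 4.0, 0.0, 15.0),
    "pdq39_emotional_wellbeing": ("truncnorm", 17.0, 10.0, 0.0, 50.0),
    "oci": ("truncnorm", 6.0, 5.0, 0.0, 25.0),
}


@dataclass
class CohortGenSpec:
    n_subjects: int = 500
    beta_theta: float = -3.16
    beta_exec: float = 0.54
    beta_wm: float = 0.19
    intercept: float = -0.3
    noise_sd: float = 0.84
    seed: int = 0
    covariate_distributions: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    domain_mean: float = -0.1          # latent domain-score location
    domain_sd: float = 0.9             # latent domain-score spread
    test_scatter: float = 0.4          # within-domain test scatter (z units)

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GeneratedCohort:
    baseline: pd.DataFrame         # demographics + clinical + 14 raw tests + MMSE
    followup: pd.DataFrame         # 14 raw tests + MMSE
    norms: pd.DataFrame
    truth: pd.DataFrame            # planted latents and outcome per subject


def _draw(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "truncnorm":
        _, m, s, lo, hi = law
        return np.clip(rng.normal(m, s, n), lo, hi)
    if kind == "trunclognorm":
        _, median, sig, lo, hi = law
        return np.clip(rng.lognormal(np.log(median), sig, n), lo, hi)
    if kind == "bernoulli":
        return (rng.random(n) < law[1]).astype(float)
    raise ValueError(f"unknown law {kind!r}")


def generate_cohort(spec: CohortGenSpec, eeg_features: pd.DataFrame) -> GeneratedCohort:
    """Two-visit cohort tables with the outcome planted on known coefficients.

    ``eeg_features`` must contain one row per subject with at least a
    ``grmp_theta`` column (e.g. from :func:`sample_spectral_features` or from
    the full EEG pipeline).
    """
    n = spec.n_subjects
    if len(eeg_features) != n:
        raise ValueError(
            f"feature rows ({len(eeg_features)}) do not match n_subjects ({n})"
        )
    if "grmp_theta" not in eeg_features.columns:
        raise ValueError("eeg_features must contain a 'grmp_theta' column")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 20)))
    idx = eeg_features.index

    baseline = pd.DataFrame(index=idx)
    for name, law in spec.covariate_distributions.items():
        baseline[name] = _draw(rng, law, n)
    baseline["mmse"] = np.clip(np.round(rng.normal(29.0, 1.3, n)), 24, 30)

    norms = generate_norms(TESTS, seed=spec.seed)

    # latent domain scores; per-test scatter is centred within each domain so
    # the domain score (mean of member z-scores) equals the latent exactly
    domains = ["attention", "executive", "fluency", "long_term_memory",
               "working_memory", "visuospatial"]
    latent = pd.DataFrame(
        rng.normal(spec.domain_mean, spec.domain_sd, (n, len(domains))),
        index=idx, columns=domains,
    )
    z_bl = pd.DataFrame(index=idx, columns=list(TESTS), dtype=float)
    for d in domains:
        members = tests_in_domain(d)
        e = rng.normal(0.0, spec.test_scatter, (n, len(members)))
        e -= e.mean(axis=1, keepdims=True)
        for j, t in enumerate(members):
            z_bl[t] = latent[d].to_numpy() + e[:, j]

    theta = eeg_features["grmp_theta"].to_numpy()
    eps = rng.normal(0.0, spec.noise_sd, n)
    t_change = (
        spec.intercept
        + spec.beta_theta * theta
        + spec.beta_exec * latent["executive"].to_numpy()
        + spec.beta_wm * latent["working_memory"].to_numpy()
        + eps
    )
    z_fu = z_bl.add(t_change, axis=0)

    def z_to_raw(z: pd.DataFrame) -> pd.DataFrame:
        raw = pd.DataFrame(index=idx)
        for t in TESTS:
            m, s, hib = norms.loc[t, "mean"], norms.loc[t, "sd"], norms.loc[t, "higher_is_better"]
            raw[t] = m + s * z[t] if hib else m - s * z[t]
        return raw

    baseline = pd.concat([baseline, z_to_raw(z_bl)], axis=1)
    followup = z_to_raw(z_fu)

    sd_t = t_change.std(ddof=1)
    ci_expected = t_change / sd_t if sd_t > 0 else np.zeros(n)
    followup["mmse"] = np.clip(
        np.round(27.5 + 2.0 * ci_expected + rng.normal(0.0, 0.8, n)), 0, 30
    )

    truth = pd.DataFrame(
        {
            "grmp_theta": theta,
            "executive": latent["executive"],
            "working_memory": latent["working_memory"],
            "planted_change": t_change,
            "expected_ci_ocs": ci_expected,
        },
        index=idx,
    )
    return GeneratedCohort(baseline=baseline, followup=followup, norms=norms, truth=truth)
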