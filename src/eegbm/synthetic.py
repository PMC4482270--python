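"""Synthetic scalp-EEG cohorts with known ground truth.

Each synthetic subject is a 19-channel 10-20 recording built from four
ingredients:

* a 1/f^2-like broadband background (white noise spectrally shaped to a
  target log-log slope, flat below 1 Hz to keep power finite);
* a narrowband posterior-dominant alpha rhythm, independent per channel,
  whose amplitude follows a linear anterior->posterior taper between
  ``anterior_alpha_amp`` and ``posterior_alpha_amp`` — the squared amplitude
  ratio is the planted spectral gradient the peak alpha ratio should recover;
* lagged shared sources planted on chosen derivation pairs.  The desired
  derivation-space signal is mapped back to channel space through the
  montage pseudoinverse, so the source appears on the targeted derivations
  with (almost) no crosstalk onto derivations sharing an electrode — the
  ground-truth edge set lives in exactly the space the network inference
  operates on;
* zero-lag shared sources on chosen pairs, emulating common-source /
  volume-conduction coupling that the zero-lag exclusion should remove.

Artifact intervals are overwritten with high-amplitude noise and annotated
(never silently deleted), so the excision logic downstream is exercised.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ANTERIOR_POSTERIOR_COORD,
    DOUBLE_BANANA,
    TEN_TWENTY_LABELS,
    pair_name,
)
from .preprocess import Recording, VALID_FS
from . import io as eio


# ---------------------------------------------------------------------------
# Subject parameters
# ---------------------------------------------------------------------------

@dataclass
class SubjectParams:
    subject_id: str = "S000"
    group_label: str = "control"          # 'ASD' or 'control'
    subtype: str = "none"                 # 'none' or 'aspergers'
    split: str = "training"               # 'training' or 'validation'
    fs: float = 200.0
    duration: float = 120.0               # seconds
    alpha_center: float = 10.0            # Hz
    alpha_band: tuple[float, float] = (8.0, 12.0)
    posterior_alpha_amp: float = 40.0     # uV (std of the occipital alpha)
    anterior_alpha_amp: float = 10.0      # uV
    background_amp: float = 20.0          # uV (broadband std)
    background_slope: float = -2.0        # target log10 P vs log10 f slope
    coupled_edges: list = field(default_factory=list)   # (pair, lag_ms, gain_uV)
    zero_lag_edges: list = field(default_factory=list)  # (pair, gain_uV)
    artifact_intervals: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.fs not in VALID_FS:
            raise ValueError(f"fs: {self.fs} not a supported rate {VALID_FS}")
        lo, hi = self.alpha_band
        if not (0.5 < lo < hi < 50.0):
            raise ValueError(f"alpha_band: {self.alpha_band} must lie within (0.5, 50) Hz")
        if self.group_label not in ("ASD", "control"):
            raise ValueError(f"group_label: {self.group_label!r}")
        for pair, lag_ms, gain in self.coupled_edges:
            if gain < 0:
                raise ValueError(f"coupled_edges: negative gain on {pair}")
        for pair, gain in self.zero_lag_edges:
            if gain < 0:
                raise ValueError(f"zero_lag_edges: negative gain on {pair}")
        last = 0.0
        for start, stop in sorted(self.artifact_intervals):
            if start < last or stop <= start or stop > self.duration:
                raise ValueError(
                    "artifact_intervals: intervals must be disjoint, ordered and "
                    f"within [0, {self.duration}] s"
                )
            last = stop

    def planted_alpha_ratio(self) -> float:
        """Posterior/anterior derivation alpha-power ratio implied by the taper.

        Channels carry independent alpha, so a derivation's alpha power is the
        sum of its two electrodes' squared amplitudes; the planted gradient is
        the mean of the four posterior/anterior pair ratios used by the peak
        alpha ratio statistic.
        """
        from .channels import RATIO_PAIRS

        def deriv_power(deriv: str) -> float:
            a, b = deriv.split("-")
            return self._amp(a) ** 2 + self._amp(b) ** 2

        return float(np.mean([
            deriv_power(post) / deriv_power(ant) for post, ant in RATIO_PAIRS
        ]))

    def _amp(self, electrode: str) -> float:
        y = ANTERIOR_POSTERIOR_COORD[electrode]
        return self.anterior_alpha_amp + (self.posterior_alpha_amp - self.anterior_alpha_amp) * y


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _shaped_noise(rng, n: int, fs: float, slope: float, f_floor: float = 1.0) -> np.ndarray:
    """Unit-variance noise whose PSD follows f^slope above f_floor, flat below."""
    white = rng.standard_normal(n)
    W = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.maximum(f, f_floor) ** (slope / 2.0)
    amp[0] = 0.0
    x = np.fft.irfft(W * amp, n)
    return x / x.std()


def _band_noise(rng, n: int, fs: float, bands) -> np.ndarray:
    """Unit-variance noise limited to one or more bands (hard FFT mask)."""
    if np.isscalar(bands[0]):
        bands = (bands,)
    white = rng.standard_normal(n)
    W = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    keep = np.zeros(f.shape, bool)
    for lo, hi in bands:
        keep |= (f >= lo) & (f <= hi)
    W[~keep] = 0.0
    x = np.fft.irfft(W, n)
    return x / x.std()


COUPLING_BAND = (2.0, 25.0)   # band of the planted lagged shared sources (Hz)
# The common (zero-lag) sources need a broad total bandwidth — a narrowband
# common source's own autocorrelation inflates the Bartlett variance of its
# pair's zero-lag correlation, capping the standardized statistic near the
# detection threshold no matter how strong the source is — but must stay
# clear of the 8-14 Hz window searched by the peak alpha ratio, since the
# default zero-lag pairs sit on ratio derivations.  Hence a notched band.
ZERO_LAG_BAND = ((2.0, 6.5), (15.5, 20.0))

#: Coupling gain (uV) at which a planted lagged edge is detected in > 90 %
#: of 2 s epochs under the default subject conditions.
STRONG_EDGE_GAIN = 55.0


def generate_subject(params: SubjectParams) -> Recording:
    """Synthesize one subject's Recording from its parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    n_ch = len(TEN_TWENTY_LABELS)

    samples = np.empty((n, n_ch))
    for c, lab in enumerate(TEN_TWENTY_LABELS):
        bg = _shaped_noise(rng, n, fs, params.background_slope) * params.background_amp
        alpha = _band_noise(rng, n, fs, params.alpha_band) * params._amp(lab)
        samples[:, c] = bg + alpha

    # planted coupling, exact in derivation space via the montage pseudoinverse
    montage = DOUBLE_BANANA
    deriv_names = montage.derivation_names
    D = np.zeros((n, len(deriv_names)))
    planted_any = False
    for (d1, d2), lag_ms, gain in params.coupled_edges:
        if gain == 0:
            continue
        src = _band_noise(rng, n, fs, COUPLING_BAND) * gain
        lag = int(round(lag_ms / 1000.0 * fs))
        D[:, deriv_names.index(d1)] += src
        D[:, deriv_names.index(d2)] += np.roll(src, lag)
        planted_any = True
    for (d1, d2), gain in params.zero_lag_edges:
        if gain == 0:
            continue
        src = _band_noise(rng, n, fs, ZERO_LAG_BAND) * gain
        D[:, deriv_names.index(d1)] += src
        D[:, deriv_names.index(d2)] += src
        planted_any = True
    if planted_any:
        samples += D @ np.linalg.pinv(montage.matrix()).T

    # artifacts: overwrite with high-amplitude noise and annotate
    for start, stop in params.artifact_intervals:
        a, b = int(round(start * fs)), int(round(stop * fs))
        samples[a:b] = rng.standard_normal((b - a, n_ch)) * 8 * params.background_amp

    return Recording(
        subject_id=params.subject_id,
        fs=fs,
        samples=samples,
        channel_labels=TEN_TWENTY_LABELS,
        group_label=params.group_label,
        subtype=params.subtype,
        split=params.split,
        artifact_annotations=list(params.artifact_intervals),
        state_segments=[(0.0, params.duration, "wake")],
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Derivation pairs with group-differential lagged coupling (stronger in
#: controls).  All default planted pairs couple derivations from different
#: hemispheres (or the midline): the double-banana montage matrix has rank
#: 16 (each hemisphere's lateral and parasagittal chains sum to the same
#: Fp->O difference), so pseudoinverse planting leaks a -1/8 copy of the
#: source onto same-hemisphere chain-mates; cross-hemisphere pairs have
#: structurally zero mutual leakage, keeping the planted edges free of
#: spurious zero-lag correlation.  They also avoid the eight ratio-pair
#: derivations so that the spectral and network effects are planted
#: independently.
DIFFERENTIAL_EDGES: tuple[tuple[str, str], ...] = (
    ("F7-T3", "F4-C4"),
    ("F3-C3", "F8-T4"),
    ("T3-T5", "C4-P4"),
    ("C3-P3", "T4-T6"),
    ("F3-C3", "Cz-Pz"),
)

#: Pairs coupled equally in both groups (baseline density).
COMMON_EDGES: tuple[tuple[str, str], ...] = (
    ("F3-C3", "F4-C4"),
    ("Fz-Cz", "T4-T6"),
    ("C3-P3", "C4-P4"),
)

#: Pairs with zero-lag common theta-band sources (volume-conduction
#: emulation); placed on ratio derivations, whose alpha-band content they
#: leave untouched (the source band lies below 8 Hz).
ZERO_LAG_EDGES: tuple[tuple[str, str], ...] = (
    ("P3-O1", "P4-O2"),
    ("Fp1-F3", "Fp2-F4"),
)


@dataclass
class GroupEffects:
    """Planted per-group effect sizes (amplitudes in uV)."""

    posterior_alpha_amp: float
    anterior_alpha_amp: float
    differential_gain: float
    common_gain: float = 35.0
    zero_lag_gain: float = 90.0


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic two-arm cohort.

    Group sizes default to the clinical study's arms: 13 ASD / 24 control in
    the training (exploratory) split and 14 ASD / 31 control in the
    validation split, with 3 and 2 Asperger's subjects among the ASD groups
    respectively.
    """

    n_training: tuple[int, int] = (13, 24)       # (ASD, control)
    n_validation: tuple[int, int] = (14, 31)
    n_aspergers: tuple[int, int] = (3, 2)        # per split, within ASD
    fs: float = 200.0
    duration: float = 120.0
    coupling_lag_ms: float = 50.0
    jitter: float = 0.15                         # lognormal sigma on amps/gains
    n_artifacts: int = 2
    artifact_seconds: float = 2.0
    # Both groups share the posterior alpha amplitude; the gradient difference
    # is planted anteriorly (higher anterior alpha in the ASD-like group), so
    # group-differential narrowband power — which would otherwise produce
    # group-differential false-edge rates on alpha-rich posterior pairs — is
    # kept away from the posterior derivations.
    effects: dict = field(default_factory=lambda: {
        "control": GroupEffects(posterior_alpha_amp=30.0, anterior_alpha_amp=3.0,
                                differential_gain=40.0),
        "ASD": GroupEffects(posterior_alpha_amp=30.0, anterior_alpha_amp=10.0,
                            differential_gain=8.0),
        "aspergers": GroupEffects(posterior_alpha_amp=30.0, anterior_alpha_amp=6.0,
                                  differential_gain=18.0),
    })
    seed: int = 0


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, reproducible from (config, seed)."""

    config: CohortConfig
    subjects: dict                       # subject_id -> SubjectParams
    group_alpha_ratio: dict              # group -> planted posterior/anterior ratio
    group_edge_gains: dict               # group -> {pair name -> mean gain}
    differential_edges: tuple = DIFFERENTIAL_EDGES


def _subject_params(cfg: CohortConfig, sid: str, group: str, subtype: str,
                    split: str, rng, seed: int) -> SubjectParams:
    eff = cfg.effects["aspergers" if subtype == "aspergers" else group]
    j = lambda: float(np.exp(rng.normal(0.0, cfg.jitter)))
    coupled = [
        (pair, cfg.coupling_lag_ms, eff.differential_gain * j())
        for pair in DIFFERENTIAL_EDGES
    ] + [(pair, cfg.coupling_lag_ms, eff.common_gain * j()) for pair in COMMON_EDGES]
    zero_lag = [(pair, eff.zero_lag_gain * j()) for pair in ZERO_LAG_EDGES]
    artifacts = []
    hi = cfg.duration - 5.0 - cfg.artifact_seconds
    if cfg.n_artifacts and hi > 5.0:
        starts = np.sort(rng.uniform(5.0, hi, cfg.n_artifacts))
        for s in starts:
            if artifacts and s < artifacts[-1][1] + 2.0:
                continue  # keep intervals disjoint with a clean gap
            artifacts.append((float(s), float(s + cfg.artifact_seconds)))
    return SubjectParams(
        subject_id=sid,
        group_label=group,
        subtype=subtype,
        split=split,
        fs=cfg.fs,
        duration=cfg.duration,
        posterior_alpha_amp=eff.posterior_alpha_amp * j(),
        anterior_alpha_amp=eff.anterior_alpha_amp * j(),
        coupled_edges=coupled,
        zero_lag_edges=zero_lag,
        artifact_intervals=artifacts,
        seed=seed,
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> tuple[list[Recording], CohortTruth]:
    """Generate the full two-arm cohort and its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    specs = []
    for split, (n_asd, n_ctrl), n_asp in (
        ("training", config.n_training, config.n_aspergers[0]),
        ("validation", config.n_validation, config.n_aspergers[1]),
    ):
        if n_asd <= 0 or n_ctrl <= 0:
            raise ValueError(f"group sizes must be positive in the {split} split")
        for k in range(n_asd):
            subtype = "aspergers" if k < n_asp else "none"
            specs.append(("ASD", subtype, split))
        for _ in range(n_ctrl):
            specs.append(("control", "none", split))

    recordings, subjects = [], {}
    for i, (group, subtype, split) in enumerate(specs):
        sid = f"S{i:03d}"
        seed = int(rng.integers(0, 2**31 - 1))
        params = _subject_params(config, sid, group, subtype, split, rng, seed)
        subjects[sid] = params
        recordings.append(generate_subject(params))

    group_ratio, group_gains = {}, {}
    for group in ("control", "ASD"):
        members = [p for p in subjects.values() if p.group_label == group]
        group_ratio[group] = float(np.mean([p.planted_alpha_ratio() for p in members]))
        gains: dict[str, list] = {}
        for p in members:
            for pair, _, gain in p.coupled_edges:
                gains.setdefault(pair_name(pair), []).append(gain)
        group_gains[group] = {k: float(np.mean(v)) for k, v in gains.items()}

    truth = CohortTruth(
        config=config,
        subjects=subjects,
        group_alpha_ratio=group_ratio,
        group_edge_gains=group_gains,
    )
    return recordings, truth


def write_fixture(recordings, directory, fmt: str = "delimited",
                  truth: CohortTruth | None = None) -> None:
    """Write a cohort as per-subject (signal, annotation, metadata) file sets."""
    for rec in recordings:
        seed = truth.subjects[rec.subject_id].seed if truth else None
        eio.write_recording(rec, directory, fmt=fmt, seed=seed)
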