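"""Synthetic EEG epochs and RDMs with known ground-truth model structure.

Stands in for the study's recordings so every downstream stage (neural
RDMs, noise ceiling, Bayesian RSA) can be exercised with a recoverable
ground truth.  The generator controls the correlation-distance geometry
directly: a target letter-by-letter similarity matrix S is built as a
weighted combination of (min-max normalised) model RDMs, projected to the
nearest positive semi-definite matrix, and per-letter multichannel
patterns are drawn as Gaussians with covariance S across letters.  Signal
is injected only inside a configurable latency window (so time-resolved
analyses see a localised effect) and per-trial Gaussian noise is added at
a stated signal-to-noise ratio.

Defaults mirror the study's scale: 14 analysed participants, 25 trials
per letter, 30 channels, 1000 Hz, epochs from -200 to 1000 ms, signal in
150-225 ms.  ``snr`` is the ratio of per-sample signal SD to per-sample
noise SD.  No realistic EEG structure beyond this (no 1/f noise, lead
fields or artefacts) is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphetic import RDM, RankRDM, rank_transform_rdm
from .neural import DEFAULT_ROI, EpochSet

__all__ = [
    "SynthConfig",
    "target_similarity_from_models",
    "synth_epochs",
    "synth_rdm_set",
    "synth_rank_vectors",
]


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for the synthetic generator."""

    n_participants: int = 14
    trials_per_letter: int = 25
    n_channels: int = 30
    sfreq: float = 1000.0
    epoch_span_ms: tuple[float, float] = (-200.0, 1000.0)
    weights: tuple[float, ...] = (0.6, 0.2)
    snr: float = 1.0
    signal_window_ms: tuple[float, float] = (150.0, 225.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.epoch_span_ms[0] >= self.epoch_span_ms[1]:
            raise ValueError("epoch span must be increasing")

    @property
    def n_samples(self) -> int:
        span = self.epoch_span_ms[1] - self.epoch_span_ms[0]
        return int(round(span * self.sfreq / 1000.0))

    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == len(DEFAULT_ROI):
            return DEFAULT_ROI
        return tuple(f"CH{i + 1:03d}" for i in range(self.n_channels))


def _minmax_triangle(rdm: RDM) -> np.ndarray:
    """RDM values min-max normalised over the lower triangle."""
    vals = rdm.values.copy()
    tri = rdm.lower_triangle()
    lo, hi = tri.min(), tri.max()
    if hi > lo:
        vals = (vals - lo) / (hi - lo)
    np.fill_diagonal(vals, 0.0)
    return np.clip(vals, 0.0, 1.0)


def target_similarity_from_models(
    model_rdms: list[RDM], weights: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Target letter similarity (and dissimilarity) from weighted models.

    The composite dissimilarity is ``D* = sum_i w_i * minmax(RDM_i)``;
    off-diagonal similarity is ``sum_i w_i * (1 - minmax(RDM_i))`` with a
    unit diagonal, so zero weights give zero off-diagonal similarity
    (pure noise target).  The similarity matrix is projected to the
    nearest positive semi-definite matrix by eigenvalue clipping and
    rescaled to a unit diagonal.

    Returns ``(S, D*)``.
    """
    if sum(weights) > 1 + 1e-12:
        raise ValueError("weights must sum to at most 1")
    if len(model_rdms) != len(weights):
        raise ValueError("one weight per model RDM")
    labels = model_rdms[0].labels if model_rdms else ()
    for r in model_rdms:
        if r.labels != labels:
            raise ValueError("model RDMs must be label-aligned")
    n = len(labels)
    d_star = np.zeros((n, n))
    s = np.eye(n)
    for rdm, w in zip(model_rdms, weights):
        norm = _minmax_triangle(rdm)
        d_star += w * norm
        off = w * (1.0 - norm)
        np.fill_diagonal(off, 0.0)
        s = s + off
    # PSD projection by eigenvalue clipping, then unit-diagonal rescale
    evals, evecs = np.linalg.eigh(s)
    s_psd = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    diag = np.sqrt(np.clip(np.diag(s_psd), 1e-12, None))
    s_psd = s_psd / np.outer(diag, diag)
    np.fill_diagonal(s_psd, 1.0)
    return s_psd, d_star


def synth_epochs(cfg: SynthConfig, model_rdms: list[RDM]) -> EpochSet:
    """Generate labelled epochs whose in-window pattern geometry follows
    the weighted model RDMs.

    Per participant, latent letter patterns are drawn with covariance S
    across letters, independently for every channel x in-window sample;
    each trial adds the letter's pattern (inside the signal window only)
    to white Gaussian noise of unit SD, with the pattern scaled by
    ``snr``.  Deterministic per ``cfg.seed``.
    """
    s_target, _ = target_similarity_from_models(model_rdms, cfg.weights)
    labels_set = model_rdms[0].labels
    n_letters = len(labels_set)
    rng = np.random.default_rng(cfg.seed)

    n_samples = cfg.n_samples
    t_ms = cfg.epoch_span_ms[0] + np.arange(n_samples) * 1000.0 / cfg.sfreq
    in_win = (t_ms >= cfg.signal_window_ms[0]) & (t_ms < cfg.signal_window_ms[1])
    n_win = int(in_win.sum())
    if n_win == 0:
        raise ValueError("signal window contains no samples")

    # jitter guards the Cholesky against exactly-singular targets
    chol = np.linalg.cholesky(s_target + 1e-9 * np.eye(n_letters))

    labels = np.repeat(np.array(labels_set, dtype=object), cfg.trials_per_letter)
    n_trials = labels.size
    data = np.empty((cfg.n_participants, n_trials, cfg.n_channels, n_samples))
    for p in range(cfg.n_participants):
        z = rng.standard_normal((n_letters, cfg.n_channels, n_win))
        patterns = np.einsum("lk,kcs->lcs", chol, z)  # cov S across letters
        noise = rng.standard_normal((n_trials, cfg.n_channels, n_samples))
        data[p] = noise
        for li in range(n_letters):
            idx = np.flatnonzero(labels == labels_set[li])
            data[p][np.ix_(idx, np.arange(cfg.n_channels), np.flatnonzero(in_win))] += (
                cfg.snr * patterns[li][None, :, :]
            )
    return EpochSet(
        data=data,
        labels=labels.astype(str),
        channel_names=cfg.channel_names(),
        sfreq=cfg.sfreq,
        t0=cfg.epoch_span_ms[0],
    )


def synth_rdm_set(
    cfg: SynthConfig,
    model_rdms: list[RDM],
    noise_sd: float | None = None,
) -> list[RankRDM]:
    """Fast shortcut generator: per-participant rank RDMs from the target.

    Perturbs the composite dissimilarity D* with exchangeable pair-level
    Gaussian noise (SD ``noise_sd``, default ``1 / snr`` or 1 when
    ``snr == 0``) independently per participant, then rank transforms.
    With zero noise every participant's RankRDM equals rank(D*).
    """
    _, d_star = target_similarity_from_models(model_rdms, cfg.weights)
    if noise_sd is None:
        noise_sd = 1.0 / cfg.snr if cfg.snr > 0 else 1.0
    labels = model_rdms[0].labels
    n = len(labels)
    i, j = np.tril_indices(n, k=-1)
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_participants):
        vals = np.zeros((n, n))
        tri = d_star[i, j] + noise_sd * rng.standard_normal(i.size)
        tri = tri - tri.min()  # keep the RDM non-negative; ranks unchanged
        vals[i, j] = tri
        vals[j, i] = tri
        out.append(rank_transform_rdm(RDM(labels=labels, values=vals,
                                          metric_id="synth")))
    return out


def synth_rank_vectors(
    rho: float,
    n_participants: int = 14,
    n_pairs: int = 435,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Neural/model rank-vector pairs with a known Spearman correlation.

    A shared latent model vector and per-participant neural vectors are
    drawn bivariate normal with the Pearson correlation
    ``2 sin(pi * rho / 6)`` that yields a population Spearman correlation
    of ``rho`` after rank transformation.  Returns
    ``(neural_ranks (participants x pairs), model_ranks (pairs,))`` for
    calibrating the correlation posterior against a known ground truth.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    from scipy.stats import rankdata

    r = 2.0 * np.sin(np.pi * rho / 6.0)
    rng = np.random.default_rng(seed)
    model = rng.standard_normal(n_pairs)
    eps = rng.standard_normal((n_participants, n_pairs))
    neural = r * model + np.sqrt(1.0 - r**2) * eps
    return (
        np.apply_along_axis(rankdata, 1, neural),
        rankdata(model),
    )
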