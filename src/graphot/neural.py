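"""Neural RDMs from epoched EEG.

Consumes already-epoched data (participants × trials × channels × samples,
in µV) and builds per-participant representational dissimilarity matrices:
condition-wise ERPs are averaged, amplitudes from a posterior
region-of-interest within an analysis window are concatenated end-to-end
into one pattern vector per letter, and pairwise dissimilarity is one
minus the Pearson correlation of those vectors.  RDMs are rank-transformed
for the rank-correlation RSA, and between-participant reliability is
summarised by a leave-one-out noise ceiling.  No filtering, artefact
rejection or re-referencing happens here — preprocessing is upstream.

Time windows are half-open ``[start, stop)`` in milliseconds, so the
planned-analysis window [150, 225) at 1000 Hz contains exactly 75 samples
per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graphetic import RankRDM, RDM, rank_transform_rdm

__all__ = [
    "DEFAULT_ROI",
    "EpochSet",
    "NeuralRDM",
    "average_erps",
    "pattern_vector",
    "correlation_distance_rdm",
    "noise_ceiling",
    "time_resolved_rdms",
    "epochs_to_hdf5",
    "epochs_from_hdf5",
]

#: Posterior region of interest (30 channels) used for letter-evoked
#: pattern analysis, covering temporo-parietal and occipital sites.
DEFAULT_ROI: tuple[str, ...] = (
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "TP10", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "PO9", "O1", "Oz", "O2", "PO10",
)


@dataclass(frozen=True)
class EpochSet:
    """Labelled multichannel epochs for a set of participants.

    ``data`` has shape (participants, trials, channels, samples); the
    trial structure (``labels``) is shared across participants.  ``t0``
    is the epoch start relative to stimulus onset in ms (negative for a
    pre-stimulus baseline); ``onset_delay_ms`` shifts all timestamps to
    absorb a known trigger-to-display delay at ingestion.
    """

    data: np.ndarray
    labels: np.ndarray  # (trials,) condition ids
    channel_names: tuple[str, ...]
    sfreq: float
    t0: float = -200.0
    onset_delay_ms: float = 0.0
    participant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        if data.ndim != 4:
            raise ValueError("data must be participants x trials x channels x samples")
        if labels.shape != (data.shape[1],):
            raise ValueError("labels must match the trial axis")
        if len(self.channel_names) != data.shape[2]:
            raise ValueError("channel_names must match the channel axis")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        pids = self.participant_ids or tuple(
            f"sub-{i + 1:02d}" for i in range(data.shape[0])
        )
        if len(pids) != data.shape[0]:
            raise ValueError("participant_ids must match the participant axis")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "participant_ids", pids)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def conditions(self) -> np.ndarray:
        """Unique condition ids in order of first appearance."""
        _, idx = np.unique(self.labels, return_index=True)
        return self.labels[np.sort(idx)]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample timestamps in ms relative to actual stimulus onset."""
        n = self.data.shape[3]
        return self.t0 - self.onset_delay_ms + np.arange(n) * 1000.0 / self.sfreq

    def participant_index(self, participant: str | int) -> int:
        if isinstance(participant, (int, np.integer)):
            return int(participant)
        return self.participant_ids.index(participant)


@dataclass(frozen=True)
class NeuralRDM:
    """Correlation-distance RDM for one participant, window and ROI."""

    rdm: RDM
    participant_id: str = ""
    window_ms: tuple[float, float] = (150.0, 225.0)
    roi: tuple[str, ...] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if np.any(self.rdm.values > 2 + 1e-12):
            raise ValueError("correlation distances must lie in [0, 2]")


def average_erps(epochs: EpochSet, participant: str | int) -> np.ndarray:
    """Per-condition average ERPs (conditions × channels × samples)."""
    p = epochs.participant_index(participant)
    conds = epochs.conditions
    missing = [c for c in conds if not np.any(epochs.labels == c)]
    if missing:  # pragma: no cover - conditions derive from labels
        raise ValueError(f"conditions with no epochs: {missing}")
    out = np.stack(
        [epochs.data[p, epochs.labels == c].mean(axis=0) for c in conds]
    )
    return out


def _window_slice(epochs: EpochSet, window_ms: tuple[float, float]) -> slice:
    t = epochs.times_ms
    start, stop = window_ms
    mask = (t >= start) & (t < stop)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    idx = np.flatnonzero(mask)
    return slice(int(idx[0]), int(idx[-1]) + 1)


def pattern_vector(
    erp: np.ndarray,
    epochs: EpochSet,
    roi: tuple[str, ...] = DEFAULT_ROI,
    window_ms: tuple[float, float] = (150.0, 225.0),
) -> np.ndarray:
    """Concatenated ROI amplitudes for one condition ERP.

    ``erp`` is (channels × samples) for a single condition.  ROI channels'
    amplitudes at successive time points within the half-open window are
    concatenated end-to-end, giving a vector of length
    ``len(roi) * n_samples(window)``.
    """
    unknown = [ch for ch in roi if ch not in epochs.channel_names]
    if unknown:
        raise ValueError(f"unknown ROI channels: {unknown}")
    ch_idx = [epochs.channel_names.index(ch) for ch in roi]
    sl = _window_slice(epochs, window_ms)
    block = erp[ch_idx, sl]  # (roi, samples)
    # successive time points concatenated: sample-major ordering
    return block.T.reshape(-1)


def correlation_distance_rdm(
    vectors: dict[str, np.ndarray] | None = None,
    *,
    labels: tuple[str, ...] | None = None,
    matrix: np.ndarray | None = None,
    metric_id: str = "neural:1-pearson",
) -> RDM:
    """RDM of 1 - Pearson r between per-condition pattern vectors.

    Accepts either a dict mapping condition label to vector, or
    ``labels`` plus a (conditions × features) ``matrix``.
    """
    if vectors is not None:
        labels = tuple(vectors.keys())
        matrix = np.stack([vectors[k] for k in labels])
    assert labels is not None and matrix is not None
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    sd = matrix.std(axis=1)
    if np.any(sd == 0):
        flat = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant pattern vectors (undefined correlation): {flat}")
    dist = 1.0 - np.corrcoef(matrix)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return RDM(labels=labels, values=dist, metric_id=metric_id)


def participant_rdm(
    epochs: EpochSet,
    participant: str | int,
    roi: tuple[str, ...] = DEFAULT_ROI,
    window_ms: tuple[float, float] = (150.0, 225.0),
) -> NeuralRDM:
    """ERP-average → pattern-vector → correlation-distance RDM, one participant."""
    erps = average_erps(epochs, participant)
    conds = epochs.conditions
    vectors = {
        str(c): pattern_vector(erps[k], epochs, roi=roi, window_ms=window_ms)
        for k, c in enumerate(conds)
    }
    p = epochs.participant_index(participant)
    return NeuralRDM(
        rdm=correlation_distance_rdm(vectors),
        participant_id=epochs.participant_ids[p],
        window_ms=tuple(window_ms),
        roi=tuple(roi),
    )


def all_participant_rank_rdms(
    epochs: EpochSet,
    roi: tuple[str, ...] = DEFAULT_ROI,
    window_ms: tuple[float, float] = (150.0, 225.0),
) -> list[RankRDM]:
    """Rank-transformed neural RDM for every participant."""
    return [
        rank_transform_rdm(participant_rdm(epochs, p, roi, window_ms).rdm)
        for p in range(epochs.n_participants)
    ]


def _spearman_triangles(x: np.ndarray, y: np.ndarray) -> float:
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def noise_ceiling(rdms: list[RankRDM]) -> tuple[float, float]:
    """Leave-one-out noise ceiling over participants' rank RDMs.

    Per fold, the lower bound is the Spearman correlation between the
    left-out participant's RDM and the average of the remaining
    participants' (rank-transformed) RDMs; the upper bound correlates the
    left-out RDM with the average including the left-out participant.
    The returned bounds are the fold averages.
    """
    if len(rdms) < 3:
        raise ValueError("noise ceiling needs at least 3 participants")
    tris = np.stack([r.lower_triangle() for r in rdms])  # (P, pairs)
    n = tris.shape[0]
    lowers, uppers = [], []
    mean_all = tris.mean(axis=0)
    for i in range(n):
        mean_rest = (mean_all * n - tris[i]) / (n - 1)
        lowers.append(_spearman_triangles(tris[i], mean_rest))
        uppers.append(_spearman_triangles(tris[i], mean_all))
    return float(np.mean(lowers)), float(np.mean(uppers))


def time_resolved_rdms(
    epochs: EpochSet,
    bin_ms: int = 10,
    roi: tuple[str, ...] = DEFAULT_ROI,
) -> list[tuple[tuple[float, float], list[NeuralRDM]]]:
    """Per-participant RDMs for consecutive non-overlapping time bins.

    Bins of ``bin_ms`` are tiled from the epoch start; within each bin,
    samples are concatenated exactly as in :func:`pattern_vector`.
    Returns a list of ``(window_ms, [rdm per participant])`` in temporal
    order.  ``bin_ms`` must span at least one sample.
    """
    samples_per_bin = bin_ms * epochs.sfreq / 1000.0
    if samples_per_bin < 1:
        raise ValueError("bin_ms is shorter than one sample at this sfreq")
    t_start = epochs.t0 - epochs.onset_delay_ms
    n_samples = epochs.data.shape[3]
    total_ms = n_samples * 1000.0 / epochs.sfreq
    n_bins = int(total_ms // bin_ms)
    out = []
    for k in range(n_bins):
        win = (t_start + k * bin_ms, t_start + (k + 1) * bin_ms)
        rdms = [
            participant_rdm(epochs, p, roi=roi, window_ms=win)
            for p in range(epochs.n_participants)
        ]
        out.append((win, rdms))
    return out


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def epochs_to_hdf5(epochs: EpochSet, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=[str(v).encode("utf-8") for v in epochs.labels]
        )
        f.create_dataset(
            "channels", data=[s.encode("utf-8") for s in epochs.channel_names]
        )
        f.create_dataset("sfreq", data=epochs.sfreq)
        f.create_dataset("t0", data=epochs.t0)


def epochs_from_hdf5(path: str, onset_delay_ms: float = 0.0) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=np.array([s.decode("utf-8") for s in f["labels"][()]]),
            channel_names=tuple(s.decode("utf-8") for s in f["channels"][()]),
            sfreq=float(f["sfreq"][()]),
            t0=float(f["t0"][()]),
            onset_delay_ms=onset_delay_ms,
        )
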