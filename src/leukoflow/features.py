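"""Event-intensity transforms and the patient-level cellular-composition features.

Fluorescence intensities are variance-stabilized with the arcsinh transform
(cofactor 150), the standard choice for conventional flow cytometry; scatter
channels are linearly scaled to [0, 1] by the fixed instrument range. The
patient-level representation is the fraction of events in each of the 16
cell classes, optionally concatenated with a 16 x 12 matrix of per-class
median transformed intensities (the "with channels" feature set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, FormatError, UnknownLabel
from .fcs_io import EventMatrix
from .vocab import CELL_TYPES, CELL_TYPE_INDEX, N_CELL_TYPES

#: arcsinh cofactor for fluorescence channels (instrument units).
ARCSINH_COFACTOR = 150.0
#: full-scale instrument range used to normalize scatter channels.
SCATTER_RANGE = 262_144.0


def transform_events(em: EventMatrix) -> np.ndarray:
    """Return the transformed n x 12 intensity matrix used by all models.

    Fluorescence: ``arcsinh(x / 150)``; scatter: ``x / 262144`` (clipped to at
    most 1). Strictly monotone per channel and deterministic. Negative scatter
    values are an instrument-export error and raise :class:`FormatError`.
    """
    x = em.values
    out = np.empty_like(x, dtype=np.float64)
    fl = em.panel.fluorescence_idx
    sc = em.panel.scatter_idx
    out[:, fl] = np.arcsinh(x[:, fl] / ARCSINH_COFACTOR)
    scatter = x[:, sc]
    if np.any(scatter < 0):
        raise FormatError("negative scatter intensity outside instrument range")
    out[:, sc] = np.minimum(scatter / SCATTER_RANGE, 1.0)
    return out


def inverse_transform(transformed: np.ndarray, panel) -> np.ndarray:
    """Map transformed-space values back to instrument units (simulator use)."""
    x = np.empty_like(transformed, dtype=np.float64)
    fl = panel.fluorescence_idx
    sc = panel.scatter_idx
    x[:, fl] = np.sinh(transformed[:, fl]) * ARCSINH_COFACTOR
    x[:, sc] = transformed[:, sc] * SCATTER_RANGE
    return x


@dataclass
class CompositionVector:
    """Per-sample cell-class composition: fractions, counts and optional summaries."""

    sample_id: str
    fractions: np.ndarray
    counts: np.ndarray
    channel_summary: np.ndarray | None = None
    class_present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.fractions.shape != (N_CELL_TYPES,) or self.counts.shape != (
            N_CELL_TYPES,
        ):
            raise AlignmentError("composition vectors must have 16 entries")
        n = int(self.counts.sum())
        if n < 1:
            raise AlignmentError("composition requires at least one event")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise AlignmentError("fractions must sum to 1")
        if not np.allclose(self.fractions, self.counts / n, atol=1e-12):
            raise AlignmentError("fractions must equal counts / n_events")

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    def features(self, with_summaries: bool = False) -> np.ndarray:
        """Flat feature vector: 16 fractions, plus 192 summaries if requested."""
        if not with_summaries:
            return self.fractions.copy()
        if self.channel_summary is None:
            raise AlignmentError("composition has no channel summaries attached")
        return np.concatenate([self.fractions, self.channel_summary.ravel()])


def _label_indices(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    try:
        return np.array([CELL_TYPE_INDEX[l] for l in labels], dtype=np.intp)
    except KeyError as exc:
        raise UnknownLabel(f"label {exc.args[0]!r} outside the 16-class vocabulary")


def composition_vector(labels: np.ndarray, sample_id: str = "") -> CompositionVector:
    """Exact class fractions of a per-event label vector, in fixed class order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise AlignmentError("empty label vector")
    idx = _label_indices(labels)
    counts = np.bincount(idx, minlength=N_CELL_TYPES).astype(np.int64)
    return CompositionVector(
        sample_id=sample_id,
        fractions=counts / counts.sum(),
        counts=counts,
    )


def channel_summaries(
    em: EventMatrix, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class median transformed intensity, one 12-vector per cell class.

    Returns ``(summary, present)`` where ``summary`` is 16 x 12 (zero rows for
    absent classes) and ``present`` is a 16-vector boolean mask. Medians are
    used rather than means for robustness in heavy-tailed fluorescence data.
    """
    labels = np.asarray(labels)
    if len(labels) != em.n_events:
        raise AlignmentError(
            f"{len(labels)} labels for {em.n_events} events"
        )
    t = transform_events(em)
    idx = _label_indices(labels)
    summary = np.zeros((N_CELL_TYPES, 12), dtype=np.float64)
    present = np.zeros(N_CELL_TYPES, dtype=bool)
    for c in range(N_CELL_TYPES):
        mask = idx == c
        if mask.any():
            summary[c] = np.median(t[mask], axis=0)
            present[c] = True
    return summary, present


def composition_with_summaries(
    em: EventMatrix, labels: np.ndarray
) -> CompositionVector:
    """Composition vector with the 16 x 12 per-class median summary attached."""
    cv = composition_vector(labels, sample_id=em.sample_id)
    summary, present = channel_summaries(em, labels)
    cv.channel_summary = summary
    cv.class_present = present
    return cv


def composition_table(compositions: list[CompositionVector], with_summaries: bool):
    """Stack compositions into a feature matrix (n_samples x 16 or x 208)."""
    return np.stack([cv.features(with_summaries) for cv in compositions])
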