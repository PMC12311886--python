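"""In-memory representation of a single MS/MS (fragmentation) spectrum.

A spectrum is the peak list produced by fragmenting one selected precursor
ion: parallel arrays of fragment m/z (Da) and intensity, plus the precursor
m/z and the ionization polarity. Two optional per-peak annotation arrays are
carried along: ``peak_labels`` (ground-truth fragment/noise labels, used by
the synthetic generator) and ``explained`` (boolean flags marking fragment
ions attributable to the compound's structure, e.g. by a fragmentation-tree
tool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: allowed values of the per-peak ground-truth label array
PEAK_LABELS = ("fragment", "noise", "unknown")


@dataclass
class Spectrum:
    """One MS/MS scan.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a collection.
    precursor_mz : float
        m/z of the ion selected for fragmentation (Da, > 0).
    polarity : str
        ``"positive"`` or ``"negative"``.
    mz : ndarray
        Fragment m/z values in Da, strictly increasing.
    intensity : ndarray
        Nonnegative intensities, same length as ``mz``.
    peak_labels : ndarray of str, optional
        Per-peak ground-truth label (``fragment`` / ``noise`` / ``unknown``).
    explained : ndarray of bool, optional
        Per-peak flag: ion explainable from the compound structure.
    metadata : dict
        Open key/value map (compound name, adduct, collision energy, ...).
    """

    id: str
    precursor_mz: float
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    peak_labels: np.ndarray | None = None
    explained: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"mz and intensity length mismatch: {len(self.mz)} vs {len(self.intensity)}"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"spectrum {self.id!r}: mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.id!r}: negative intensity")
        for name in ("peak_labels", "explained"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != len(self.mz):
                    raise ValueError(f"spectrum {self.id!r}: {name} length mismatch")
                setattr(self, name, arr)
        if self.peak_labels is not None:
            bad = set(np.unique(self.peak_labels)) - set(PEAK_LABELS)
            if bad:
                raise ValueError(f"unknown peak labels: {sorted(bad)}")
        if self.explained is not None:
            self.explained = self.explained.astype(bool)

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    @property
    def base_peak_intensity(self) -> float:
        """Intensity of the most intense peak."""
        if len(self.mz) == 0:
            raise ValueError("empty spectrum has no base peak")
        return float(self.intensity.max())

    def subset(self, keep: np.ndarray, id_suffix: str = "") -> "Spectrum":
        """Return a new spectrum restricted to the peaks where ``keep`` is True.

        Annotation arrays are subset in parallel; metadata is shared (shallow
        copy). Peak order (hence the strictly-increasing m/z invariant) is
        preserved.
        """
        keep = np.asarray(keep, dtype=bool)
        if len(keep) != len(self.mz):
            raise ValueError("keep mask length mismatch")
        return Spectrum(
            id=self.id + id_suffix,
            precursor_mz=self.precursor_mz,
            polarity=self.polarity,
            mz=self.mz[keep].copy(),
            intensity=self.intensity[keep].copy(),
            peak_labels=None if self.peak_labels is None else self.peak_labels[keep].copy(),
            explained=None if self.explained is None else self.explained[keep].copy(),
            metadata=dict(self.metadata),
        )

    def copy(self, **changes: Any) -> "Spectrum":
        """Return a copy, optionally overriding fields (dataclass replace)."""
        return replace(self, **changes)


def make_spectrum(
    mz,
    intensity,
    *,
    id: str = "s",
    precursor_mz: float | None = None,
    polarity: str = POSITIVE,
    peak_labels=None,
    explained=None,
    metadata: Mapping[str, Any] | None = None,
    merge_duplicates: bool = False,
) -> Spectrum:
    """Build a :class:`Spectrum` from unsorted peak arrays.

    Peaks are re-sorted by ascending m/z (stable). If ``merge_duplicates``,
    peaks with exactly equal m/z are merged by summing their intensities
    (annotations of the first member are kept); otherwise duplicates raise.
    If ``precursor_mz`` is omitted it defaults to 1 Da above the largest
    fragment, which is convenient for hand-built test spectra.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    for name, arr in (("peak_labels", peak_labels), ("explained", explained)):
        if arr is not None and len(np.asarray(arr)) != len(mz):
            raise ValueError(f"{name} length does not match mz")
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    if peak_labels is not None:
        peak_labels = np.asarray(peak_labels)[order]
    if explained is not None:
        explained = np.asarray(explained)[order]
    if len(mz) > 1 and np.any(np.diff(mz) == 0):
        if not merge_duplicates:
            raise ValueError("duplicate m/z values (pass merge_duplicates=True to sum)")
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, intensity)
        first = np.full(len(uniq), -1, dtype=int)
        for i in range(len(mz) - 1, -1, -1):
            first[inverse[i]] = i
        logger.warning("merged %d duplicate m/z peaks in %r", len(mz) - len(uniq), id)
        if peak_labels is not None:
            peak_labels = peak_labels[first]
        if explained is not None:
            explained = explained[first]
        mz, intensity = uniq, summed
    if precursor_mz is None:
        precursor_mz = float(mz[-1]) + 1.0 if len(mz) else 1.0
    return Spectrum(
        id=id,
        precursor_mz=float(precursor_mz),
        polarity=polarity,
        mz=mz,
        intensity=intensity,
        peak_labels=peak_labels,
        explained=explained,
        metadata=dict(metadata or {}),
    )
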