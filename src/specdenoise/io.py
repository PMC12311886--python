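"""Reading/writing spectra and annotations, plus library-curation filters.

MGF (Mascot generic format) is the exchange format: one ``BEGIN IONS`` /
``END IONS`` block per spectrum with a ``PEPMASS`` header and ``m/z
intensity`` peak lines. Parsing and serialization are delegated to
:mod:`pyteomics.mgf`; this module adds the domain container, polarity
inference and the quality filters used when assembling spectral libraries:

* spectral entropy below a maximum (high entropy marks noisy, low-quality
  scans),
* ion-count bounds (too few ions carry no network information, too many are
  expensive and usually contaminated),
* explained-ion ratio below a maximum (a spectrum whose ions are almost all
  structurally explained has typically been denoised or curated already).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.stats import entropy as _shannon

from .spectrum import NEGATIVE, POSITIVE, Spectrum, make_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "CurationFilterConfig",
    "read_mgf",
    "write_mgf",
    "spectral_entropy",
    "curate",
    "read_explained_table",
    "attach_explained",
    "write_explained_table",
]


@dataclass(frozen=True)
class CurationFilterConfig:
    """Bounds for library curation. All comparisons are strict.

    Defaults: entropy below 3, more than 20 and fewer than 1000 ions,
    explained-ion ratio below 0.75.
    """

    max_entropy: float = 3.0
    min_ions: int = 20
    max_ions: int = 1000
    max_explained_ratio: float = 0.75

    def __post_init__(self) -> None:
        if not (self.max_entropy > 0 and self.min_ions > 0 and self.max_ions > 0
                and self.max_explained_ratio > 0):
            raise ValueError("all curation bounds must be positive")
        if self.min_ions >= self.max_ions:
            raise ValueError("min_ions must be below max_ions")


def _infer_polarity(params: dict, block: int) -> str:
    """IONMODE field takes precedence, then the sign of CHARGE."""
    mode = params.get("ionmode")
    if mode is not None:
        mode = str(mode).strip().lower()
        if mode in ("positive", "pos", "+"):
            return POSITIVE
        if mode in ("negative", "neg", "-"):
            return NEGATIVE
        raise ValueError(f"MGF block {block}: unrecognized IONMODE {mode!r}")
    charge = params.get("charge")
    if charge:
        return POSITIVE if int(charge[0]) > 0 else NEGATIVE
    raise ValueError(f"MGF block {block}: neither IONMODE nor CHARGE present")


def read_mgf(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Peaks are re-sorted by ascending m/z if the file is unsorted; exact
    duplicate m/z values are merged by summing intensities (logged). Blocks
    with zero peaks are skipped with a warning. A malformed block or a block
    without PEPMASS raises :class:`ValueError` naming the block index.
    """
    path = os.fspath(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(path, convert_arrays=1) as reader:
        for block, raw in enumerate(reader):
            try:
                params = raw["params"]
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise ValueError("missing PEPMASS")
                precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
                mz = np.asarray(raw["m/z array"], dtype=float)
                inten = np.asarray(raw["intensity array"], dtype=float)
                if len(mz) == 0:
                    logger.warning("MGF block %d (%s): zero peaks, skipped",
                                   block, params.get("title", "?"))
                    continue
                polarity = _infer_polarity(params, block)
                meta = {k: v for k, v in params.items()
                        if k not in ("pepmass", "charge", "ionmode", "title")}
                spectra.append(make_spectrum(
                    mz, inten,
                    id=str(params.get("title", f"spectrum_{block}")),
                    precursor_mz=precursor,
                    polarity=polarity,
                    metadata=meta,
                    merge_duplicates=True,
                ))
            except ValueError as exc:
                raise ValueError(f"malformed MGF block {block} in {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | os.PathLike) -> None:
    """Write spectra as standard MGF blocks.

    Peak values are written with 12 significant digits so a read/write cycle
    is lossless well below 1e-9 relative error; the precursor m/z is written
    with ``repr`` (shortest exact decimal) and round-trips exactly.
    """
    records = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": repr(float(s.precursor_mz)),
            "charge": "1+" if s.polarity == POSITIVE else "1-",
            "ionmode": s.polarity,
        }
        params.update({k: v for k, v in s.metadata.items() if v is not None})
        records.append({"m/z array": s.mz, "intensity array": s.intensity, "params": params})
    with open(os.fspath(path), "w") as handle:
        _mgf.write(records, handle, fragment_format="%.12g %.12g", write_charges=False)


def spectral_entropy(s: Spectrum) -> float:
    """Shannon entropy (natural log) of the normalized intensity distribution.

    Intensities are normalized to sum to one and treated as a discrete
    probability distribution: ``H = -sum(p_i * ln(p_i))``. A single-peak
    spectrum has entropy 0; n equal peaks have entropy ``ln n``. The value is
    invariant to uniform intensity rescaling and to peak order.
    """
    if len(s) == 0 or not np.any(s.intensity > 0):
        raise ValueError(f"spectrum {s.id!r}: entropy undefined without positive intensities")
    return float(_shannon(s.intensity))


def explained_ratio(s: Spectrum) -> float | None:
    """Fraction of peaks flagged as structurally explained, or None if unflagged."""
    if s.explained is None:
        return None
    return float(np.mean(s.explained))


def curate(spectra: list[Spectrum], cfg: CurationFilterConfig | None = None) -> list[Spectrum]:
    """Apply the library-curation filters, preserving order.

    A spectrum is retained iff entropy < ``max_entropy``, peak count is
    strictly between ``min_ions`` and ``max_ions``, and — where explained
    flags are available — the explained-ion ratio is < ``max_explained_ratio``.
    Spectra without explained flags skip that one filter (warned once).
    """
    cfg = cfg or CurationFilterConfig()
    warned = False
    kept: list[Spectrum] = []
    for s in spectra:
        if not (cfg.min_ions < len(s) < cfg.max_ions):
            continue
        if not spectral_entropy(s) < cfg.max_entropy:
            continue
        ratio = explained_ratio(s)
        if ratio is None:
            if not warned:
                logger.warning("explained flags absent on some spectra: "
                               "explained-ratio filter skipped for those")
                warned = True
        elif not ratio < cfg.max_explained_ratio:
            continue
        kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# explained-ion sidecar table (TSV: spectrum_id, mz, explained)

def write_explained_table(spectra: list[Spectrum], path: str | os.PathLike) -> None:
    """Write per-peak explained flags as a TSV sidecar (spectrum_id, mz, explained)."""
    rows = []
    for s in spectra:
        if s.explained is None:
            continue
        for m, e in zip(s.mz, s.explained):
            rows.append((s.id, m, int(e)))
    pd.DataFrame(rows, columns=["spectrum_id", "mz", "explained"]).to_csv(
        path, sep="\t", index=False)


def read_explained_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"spectrum_id", "mz", "explained"}
    if not expected <= set(df.columns):
        raise ValueError(f"explained table must have columns {sorted(expected)}")
    return df


def attach_explained(spectra: list[Spectrum], table: pd.DataFrame,
                     tol: float = 1e-4) -> list[Spectrum]:
    """Return spectra with explained flags matched from a sidecar table.

    Each flagged m/z in the table is matched to the nearest peak of the named
    spectrum within ``tol`` Da; unmatched peaks default to not-explained.
    Table rows that match no peak are logged.
    """
    by_id = {str(sid): grp for sid, grp in table.groupby("spectrum_id")}
    out = []
    for s in spectra:
        grp = by_id.get(s.id)
        if grp is None:
            out.append(s)
            continue
        flags = np.zeros(len(s), dtype=bool)
        for mz_val, flag in zip(grp["mz"].to_numpy(float), grp["explained"].to_numpy()):
            idx = int(np.argmin(np.abs(s.mz - mz_val)))
            if abs(s.mz[idx] - mz_val) <= tol:
                if flag:
                    flags[idx] = True
            else:
                logger.warning("explained row (%s, %.4f) matches no peak within %g Da",
                               s.id, mz_val, tol)
        out.append(s.copy(explained=flags))
    return out
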