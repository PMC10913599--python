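"""Global signal removal and symmetric-ROI aggregation.

The global signal of a volume is its mean across ROIs; removal subtracts that
mean from every ROI and divides by the volume's population standard deviation
across ROIs, independently for each volume.  Three composite treatments are
supported:

* treatment 1 -- optional wide-stage removal, removal over the target ROIs,
  then averaging of symmetric (left, right) ROI pairs;
* treatment 2 -- treatment 1 followed by one more removal over the aggregated
  ROIs (every output row ends exactly mean-0, SD-1);
* treatment 3 -- the removals of treatment 1 without the symmetric averaging;
* ``none`` -- pass-through.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import ConfigurationError, DegenerateVolumeError, FormatError

logger = logging.getLogger(__name__)

TREATMENTS = ("none", "1", "2", "3")


@dataclass
class GlobalSignalTrace:
    """Per-volume mean and population SD used in one removal stage."""

    mean: np.ndarray
    sd: np.ndarray
    n_rois_used: int


@dataclass
class SymmetryMap:
    """Pairs of mirrored ROI columns plus pass-through midline columns."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def validate(self, n_columns: int) -> None:
        used = [i for pair in self.pairs for i in pair] + list(self.midline)
        if sorted(used) != list(range(n_columns)):
            raise ConfigurationError(
                f"symmetry map must cover each of {n_columns} columns exactly "
                f"once; got indices {sorted(used)}"
            )

    @property
    def n_output(self) -> int:
        return len(self.pairs) + len(self.midline)


def remove_global_signal(x: np.ndarray) -> tuple[np.ndarray, GlobalSignalTrace]:
    """Standardize each volume (row) to mean 0 and population SD 1.

    Raises :class:`DegenerateVolumeError` for any row that is constant across
    ROIs (SD 0).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigurationError("need a T x N matrix with N >= 2")
    mean = x.mean(axis=1)
    sd = x.std(axis=1)  # population divisor N
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise DegenerateVolumeError(
            f"volume(s) {bad.tolist()} are constant across ROIs (sd = 0)"
        )
    out = (x - mean[:, None]) / sd[:, None]
    return out, GlobalSignalTrace(mean=mean, sd=sd, n_rois_used=x.shape[1])


def aggregate_symmetric(x: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Average each (left, right) column pair; keep midline columns as-is.

    Output column order is the pairs in given order, then the midline
    columns in given order.
    """
    x = np.asarray(x, dtype=float)
    sym.validate(x.shape[1])
    cols = [0.5 * (x[:, i] + x[:, j]) for i, j in sym.pairs]
    cols += [x[:, i] for i in sym.midline]
    return np.column_stack(cols)


def apply_treatment(
    x: np.ndarray,
    treatment: str = "2",
    sym: SymmetryMap | None = None,
    wide: np.ndarray | None = None,
    target_columns: list[int] | None = None,
) -> np.ndarray:
    """Apply one of the composite global-signal treatments.

    ``wide``, if given, is a T x N-wide matrix (superset of columns) used for
    a first removal stage; ``target_columns`` selects the target ROIs from it.
    Without ``wide`` the first stage is skipped with a logged warning.
    """
    treatment = str(treatment)
    if treatment not in TREATMENTS:
        raise ConfigurationError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    if treatment == "none":
        return np.asarray(x, dtype=float).copy()

    if wide is not None:
        if target_columns is None:
            raise ConfigurationError(
                "target_columns is required when a wide pre-stage matrix is given"
            )
        wide_removed, _ = remove_global_signal(wide)
        x = wide_removed[:, target_columns]
    else:
        logger.warning(
            "no wide pre-stage matrix supplied; skipping the first-stage "
            "global signal removal"
        )
        x = np.asarray(x, dtype=float)

    x, _ = remove_global_signal(x)  # removal over the target ROIs

    if treatment == "3":
        return x

    if sym is None:
        raise ConfigurationError(
            f"treatment {treatment} requires a symmetry map"
        )
    x = aggregate_symmetric(x, sym)
    if treatment == "2":
        x, _ = remove_global_signal(x)
    return x


def load_symmetry_map(path) -> SymmetryMap:
    """Read a symmetry map CSV with columns ``roi_index,partner_or_MID``.

    Each pair is listed once (on its lower index row); midline rows carry the
    token ``MID``.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    with open(path) as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].strip().lower() == "roi_index":
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            idx = int(row[0])
            partner = row[1].strip()
            if partner.upper() == "MID":
                midline.append(idx)
            else:
                pairs.append((idx, int(partner)))
    return SymmetryMap(pairs=pairs, midline=midline)
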