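"""Flock-level performance records.

A *flock record* is one row of a commercial broiler integration's weekly
performance table: body weight (BW, g), cumulative feed intake (FI, g),
cumulative feed conversion ratio (FCR, g feed : g BW), within-week mortality
and cumulative mortality (%), observed at placement (0 d) and weekly up to
slaughter age (35 d).  FI, FCR and the mortality series are undefined at
age 0 and stored as NaN there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_AGES: tuple[int, ...] = (0, 7, 14, 21, 28, 35)
SEXES: tuple[str, str] = ("male", "female")
EFFICIENCIES: tuple[str, str] = ("HE", "LE")


class ValidationError(ValueError):
    """A record or dataset violates the flock-table contract."""


@dataclass
class WeeklySeries:
    """Weekly performance series for one flock.

    All arrays are aligned to ``ages``.  ``fi``, ``fcr``, ``week_mort`` and
    ``cum_mort`` hold NaN at age 0, where they are undefined.  FCR is stored
    as supplied by the source, never recomputed from FI/BW (integrators may
    or may not mortality-adjust it).
    """

    ages: tuple[int, ...] = DEFAULT_AGES
    bw: np.ndarray = field(default_factory=lambda: np.full(len(DEFAULT_AGES), np.nan))
    fi: np.ndarray = field(default_factory=lambda: np.full(len(DEFAULT_AGES), np.nan))
    fcr: np.ndarray = field(default_factory=lambda: np.full(len(DEFAULT_AGES), np.nan))
    week_mort: np.ndarray = field(default_factory=lambda: np.full(len(DEFAULT_AGES), np.nan))
    cum_mort: np.ndarray = field(default_factory=lambda: np.full(len(DEFAULT_AGES), np.nan))

    def __post_init__(self) -> None:
        self.ages = tuple(int(a) for a in self.ages)
        n = len(self.ages)
        for name in ("bw", "fi", "fcr", "week_mort", "cum_mort"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n},) to match ages"
                )
            setattr(self, name, arr)

    def problems(self) -> list[str]:
        """Return human-readable contract violations (empty list if valid)."""
        out: list[str] = []
        ages = np.asarray(self.ages)
        if len(ages) < 2 or ages[0] != 0:
            out.append("ages must start at 0")
        if np.any(np.diff(ages) <= 0):
            out.append("ages not strictly increasing")

        # completeness: bw at every age; the rest at every age > 0
        if np.any(~np.isfinite(self.bw)):
            out.append("missing value")
        else:
            if np.any(self.bw <= 0):
                out.append("non-positive body weight")
        later = slice(1, None)
        for name in ("fi", "fcr", "week_mort", "cum_mort"):
            if np.any(~np.isfinite(getattr(self, name)[later])):
                out.append("missing value")
                break

        fi = self.fi[later]
        if np.all(np.isfinite(fi)) and np.any(np.diff(fi) < 0):
            out.append("feed intake decreasing")
        for name in ("week_mort", "cum_mort"):
            v = getattr(self, name)[later]
            if np.all(np.isfinite(v)) and (np.any(v < 0) or np.any(v > 100)):
                out.append(f"{name} outside [0, 100]")
        cm = self.cum_mort[later]
        if np.all(np.isfinite(cm)) and np.any(np.diff(cm) < 0):
            out.append("inconsistent mortality")
        return out

    def is_complete(self) -> bool:
        return not self.problems()

    def copy(self) -> "WeeklySeries":
        return WeeklySeries(
            ages=self.ages,
            bw=self.bw.copy(),
            fi=self.fi.copy(),
            fcr=self.fcr.copy(),
            week_mort=self.week_mort.copy(),
            cum_mort=self.cum_mort.copy(),
        )


@dataclass
class FlockRecord:
    """One flock: identity, sex, and its weekly performance series."""

    flock_id: str
    sex: str
    series: WeeklySeries

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def fcr35(self) -> float:
        """Cumulative FCR at the last observed age (35 d by default)."""
        return float(self.series.fcr[-1])

    def copy(self) -> "FlockRecord":
        return replace(self, series=self.series.copy())


def equal_records(a: FlockRecord, b: FlockRecord, atol: float = 5e-4) -> bool:
    """Field-wise equality at the declared 3-decimal storage precision."""
    if a.flock_id != b.flock_id or a.sex != b.sex or a.series.ages != b.series.ages:
        return False
    for name in ("bw", "fi", "fcr", "week_mort", "cum_mort"):
        x, y = getattr(a.series, name), getattr(b.series, name)
        if not np.allclose(x, y, atol=atol, rtol=0.0, equal_nan=True):
            return False
    return True
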