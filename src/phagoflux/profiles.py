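"""Piecewise-linear recruitment profiles.

A :class:`KineticProfile` describes the fold-enrichment of a membrane
reporter on a single phagosome or macropinosome as a function of time
after engulfment: baseline (1.0) until ``t_on``, a linear rise to
``e_max`` at ``t_peak``, a plateau until ``t_plateau_end``, a linear
fall back to baseline at ``t_off``, and baseline thereafter.  The shape
is the simplest one consistent with reporters that are recruited,
persist, and are then removed; the named presets encode the timings
observed for the PI(3,5)P2 reporter SnxA and for PIKfyve itself on
*Dictyostelium* phagosomes and macropinosomes.

Times are seconds after engulfment; enrichment is dimensionless
(1.0 = indistinguishable from cytosol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticProfile", "PROFILE_PRESETS", "get_preset"]


@dataclass(frozen=True)
class KineticProfile:
    """Trapezoidal fold-enrichment profile for one reporter channel.

    Parameters
    ----------
    t_on : float
        Time after engulfment (s) at which enrichment begins rising.
    t_peak : float
        Time (s) of maximal enrichment.
    t_plateau_end : float
        Time (s) at which the decline begins.
    t_off : float
        Time (s) at which enrichment returns to baseline.
    e_max : float
        Peak fold-enrichment, >= 1.  ``e_max == 1`` gives a flat
        (never-recruited) profile, used for negative controls.
    """

    t_on: float
    t_peak: float
    t_plateau_end: float
    t_off: float
    e_max: float = 2.5
    baseline: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not (self.t_on <= self.t_peak <= self.t_plateau_end <= self.t_off):
            raise ValueError(
                "profile breakpoints must satisfy "
                "t_on <= t_peak <= t_plateau_end <= t_off, got "
                f"{self.t_on}, {self.t_peak}, {self.t_plateau_end}, {self.t_off}"
            )
        if self.e_max < self.baseline:
            raise ValueError(f"e_max ({self.e_max}) must be >= baseline ({self.baseline})")

    def __call__(self, t):
        """Evaluate the profile at time(s) ``t`` (s after engulfment).

        Total function: returns ``baseline`` for all t outside
        [t_on, t_off] (including negative times), ``e_max`` on
        [t_peak, t_plateau_end], and linear interpolation in between.
        """
        t_in = np.asarray(t, dtype=float)
        t = np.atleast_1d(t_in)
        out = np.full(t.shape, self.baseline)
        # plateau is a closed interval so instantaneous rises/falls
        # (t_on == t_peak) still reach e_max at the breakpoint itself
        plateau = (t >= self.t_peak) & (t <= self.t_plateau_end)
        out[plateau] = self.e_max
        rise = (t >= self.t_on) & (t < self.t_peak)
        if self.t_peak > self.t_on:
            frac = (t[rise] - self.t_on) / (self.t_peak - self.t_on)
            out[rise] = self.baseline + frac * (self.e_max - self.baseline)
        fall = (t > self.t_plateau_end) & (t <= self.t_off)
        if self.t_off > self.t_plateau_end:
            frac = (self.t_off - t[fall]) / (self.t_off - self.t_plateau_end)
            out[fall] = self.baseline + frac * (self.e_max - self.baseline)
        return float(out[0]) if t_in.ndim == 0 else out

    @property
    def half_rise_time(self) -> float:
        """Time at which the rising edge crosses halfway to ``e_max``."""
        return 0.5 * (self.t_on + self.t_peak)

    @property
    def half_fall_time(self) -> float:
        """Time at which the falling edge crosses halfway back down."""
        return 0.5 * (self.t_plateau_end + self.t_off)

    @property
    def is_flat(self) -> bool:
        return self.e_max <= self.baseline

    def support_above(self, level: float) -> tuple[float, float] | None:
        """Interval of times where the profile value is >= ``level``.

        Returns None for flat profiles or levels above ``e_max``.
        """
        if self.is_flat or level > self.e_max:
            return None
        if level <= self.baseline:
            return (self.t_on, self.t_off)
        frac = (level - self.baseline) / (self.e_max - self.baseline)
        t_lo = self.t_on + frac * (self.t_peak - self.t_on)
        t_hi = self.t_off - frac * (self.t_off - self.t_plateau_end)
        return (t_lo, t_hi)


#: Named presets.  Timings (seconds after engulfment) encode the
#: observed behaviour: SnxA arrives on phagosomes ~2 min after
#: engulfment (half-max of the rise at 120 s) and is retained for a
#: further ~20 min; on macropinosomes it peaks at 4 min and is removed
#: by 5-6 min; PIKfyve itself arrives within 60 s and departs around
#: 4 min unless inhibited with apilimod, in which case it is retained
#: through the end of the movie.  Peak magnitudes (e_max) are generator
#: choices: the source traces report fold change on an arbitrary scale.
PROFILE_PRESETS: dict[str, KineticProfile] = {
    "snxa_phagosome": KineticProfile(90.0, 150.0, 1290.0, 1350.0, e_max=2.5),
    "snxa_macropinosome": KineticProfile(120.0, 240.0, 240.0, 330.0, e_max=2.5),
    "pikfyve_untreated": KineticProfile(60.0, 90.0, 180.0, 240.0, e_max=2.5),
    "pikfyve_apilimod": KineticProfile(60.0, 120.0, 1e9, 1e9 + 60.0, e_max=2.5),
    "pikfyve_null": KineticProfile(120.0, 240.0, 240.0, 330.0, e_max=1.0),
}


def get_preset(name: str) -> KineticProfile:
    try:
        return PROFILE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown profile preset {name!r}; available: {sorted(PROFILE_PRESETS)}"
        ) from None
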