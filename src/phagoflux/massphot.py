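"""Mass-photometry calibration and population decomposition.

Single-molecule landing contrasts are converted to molecular mass by a
linear calibration against standards of known mass; the event-mass
distribution is then decomposed into Gaussian populations by a seeded
expectation-maximization mixture fit (k-means initialized, multiple
restarts, best likelihood kept).  Components are reported sorted by
mean with their fractions, and an information criterion per k supports
automatic choice of the number of populations.

Apparent masses below ~100 kD are flagged: the technique's mass
readout for native proteins is inaccurate in that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = ["Calibration", "MassComponent", "calibrate", "fit_mass_mixture", "select_components"]

LOW_MASS_WARNING_KD = 100.0


@dataclass
class Calibration:
    """Linear contrast-to-mass map fitted from standards."""

    slope: float  # kD per contrast unit
    intercept: float  # kD
    residuals_kd: np.ndarray
    slope_stderr: float

    def apply(self, contrast) -> np.ndarray:
        return self.slope * np.asarray(contrast, float) + self.intercept


@dataclass
class MassComponent:
    mean: float  # kD
    sd: float  # kD
    fraction: float
    low_mass_flag: bool = False  # apparent mass below the reliable range


def calibrate(standards) -> Calibration:
    """Ordinary least-squares line through (contrast, known mass kD).

    ``standards`` is an iterable of (contrast, mass) pairs or a
    DataFrame with columns ``contrast`` and ``mass``.
    """
    try:
        contrast = np.asarray(standards["contrast"], float)
        mass = np.asarray(standards["mass"], float)
    except (TypeError, IndexError, KeyError):
        arr = np.asarray(list(standards), float)
        contrast, mass = arr[:, 0], arr[:, 1]
    if contrast.size < 2:
        raise ValueError("need at least 2 standards")
    if np.unique(contrast).size < 2:
        raise ValueError("standards have identical contrasts: slope unidentifiable")
    res = stats.linregress(contrast, mass)
    fitted = res.slope * contrast + res.intercept
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residuals_kd=mass - fitted,
        slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
    )


def fit_mass_mixture(
    masses, k: int, seed: int = 0, n_init: int = 10
) -> tuple[list[MassComponent], dict]:
    """Gaussian-mixture decomposition of an event-mass list.

    EM with k-means initialization and ``n_init`` seeded restarts, best
    likelihood kept.  Returns components sorted by mean and a score
    dict with log-likelihood, AIC and BIC for the fitted k.  Degenerate
    components (collapsed onto repeated support) are reported with a
    tiny floor sd rather than zero.
    """
    x = np.asarray(masses, float).reshape(-1, 1)
    if x.size < 2 * k:
        raise ValueError(f"too few events ({x.size}) for k={k}")
    if not (1 <= k <= 10):
        raise ValueError("k must be in [1, 10]")
    if np.unique(x).size < k:
        raise ValueError(
            f"k={k} exceeds the distinct support ({np.unique(x).size} values): "
            "components would collapse"
        )
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    comps = []
    for i in order:
        mean = float(gm.means_[i, 0])
        sd = float(np.sqrt(gm.covariances_[i, 0, 0]))
        comps.append(
            MassComponent(
                mean=mean,
                sd=sd,
                fraction=float(gm.weights_[i]),
                low_mass_flag=mean < LOW_MASS_WARNING_KD,
            )
        )
    scores = {
        "log_likelihood": float(gm.score(x) * x.size),
        "aic": float(gm.aic(x)),
        "bic": float(gm.bic(x)),
        "converged": bool(gm.converged_),
    }
    return comps, scores


def select_components(
    masses, k_range=(1, 2, 3, 4), seed: int = 0, n_init: int = 10
) -> tuple[int, dict[int, float]]:
    """Choose the number of populations by BIC over ``k_range``."""
    bics = {}
    for k in k_range:
        try:
            _, scores = fit_mass_mixture(masses, k, seed=seed, n_init=n_init)
        except ValueError:
            continue
        bics[k] = scores["bic"]
    if not bics:
        raise ValueError("no k in range could be fitted")
    best = min(bics, key=bics.get)
    return best, bics
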