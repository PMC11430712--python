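"""Concentration–response analysis: block fractions and Hill-curve IC50.

The model is the four-parameter logistic (Hill) equation for an inhibitor,

    response(c) = bottom + (top − bottom) / (1 + (c / IC50)^h),

fitted by least squares on log10 concentration for conditioning.  ``response``
is the fraction of control current remaining at concentration ``c`` (µM);
IC50 is the concentration producing half-maximal inhibition and ``h`` the
Hill slope.  With the paper-style 4-point design (1, 10, 20, 50 µM) the
bottom and top are constrained to 0 and 1 for identifiability; the free
4-parameter fit requires at least 5 distinct concentrations.

Usage follows the Model/Results convention::

    res = HillModel.from_dataframe(df, conc="concentration", resp="response").fit()
    res.ic50, res.bse, res.conf_int(), res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["block_fraction", "HillModel", "HillResults", "HillParams", "hill_response", "hill_fit"]


def block_fraction(current_drug: float, current_control: float) -> dict[str, float]:
    """Fold change and block fraction of a drug current relative to control.

    Returns ``{"fold_change": I_drug/I_control, "block": 1 − fold_change}``.
    """
    if current_control == 0:
        raise ValueError("control current must be nonzero")
    fold = current_drug / current_control
    return {"fold_change": fold, "block": 1.0 - fold}


def hill_response(c: np.ndarray, ic50: float, hill_slope: float, bottom: float = 0.0, top: float = 1.0) -> np.ndarray:
    """Hill (four-parameter logistic) inhibition curve."""
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill_slope)


@dataclass
class HillParams:
    """Fitted Hill-curve parameters and their standard errors."""

    bottom: float
    top: float
    ic50: float
    hill_slope: float
    se_ic50: float = np.nan
    se_hill_slope: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.converged and self.bottom > self.top:
            raise ValueError("bottom must not exceed top")


class HillModel:
    """Hill concentration–response model bound to a dose–response table."""

    def __init__(self, concentration: np.ndarray, response: np.ndarray, n_cells: np.ndarray | None = None):
        c = np.asarray(concentration, dtype=float)
        y = np.asarray(response, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1-D arrays")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be unique")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        order = np.argsort(c)
        self.concentration = c[order]
        self.response = y[order]
        self.n_cells = None if n_cells is None else np.asarray(n_cells)[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc: str = "concentration", resp: str = "response", n: str | None = None) -> "HillModel":
        return cls(df[conc].to_numpy(), df[resp].to_numpy(), df[n].to_numpy() if n and n in df else None)

    def fit(self, fix_bottom_top: bool | None = None, n_starts: int = 7) -> "HillResults":
        """Least-squares Hill fit with multi-start initialisation on log10 IC50.

        ``fix_bottom_top=None`` resolves to True for designs with fewer than
        5 distinct concentrations.  Flat or non-identifiable data yield a
        non-converged result (``converged=False``), never a silent value.
        """
        c, y = self.concentration, self.response
        if fix_bottom_top is None:
            fix_bottom_top = len(c) < 5
        n_params = 2 if fix_bottom_top else 4
        min_points = 3 if fix_bottom_top else 5
        if len(c) < min_points:
            raise ValueError(f"need >= {min_points} distinct concentrations for this design")

        if np.ptp(y) < 1e-12:  # constant response: IC50 unidentifiable
            return HillResults(self, None, None, fix_bottom_top, converged=False, message="flat response")

        logc = np.log10(c)

        def residuals(theta: np.ndarray) -> np.ndarray:
            if fix_bottom_top:
                log_ic50, h = theta
                bottom, top = 0.0, 1.0
            else:
                log_ic50, h, bottom, top = theta
            return hill_response(c, 10.0**log_ic50, h, bottom, top) - y

        starts = np.linspace(logc.min() - 0.5, logc.max() + 0.5, n_starts)
        best = None
        for s in starts:
            theta0 = [s, 1.0] if fix_bottom_top else [s, 1.0, float(y.min()), float(y.max())]
            try:
                sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            return HillResults(self, None, None, fix_bottom_top, converged=False, message="no start converged")
        if best.x[1] <= 0:  # wrong-signed slope: data not concentration-inhibited
            return HillResults(self, None, None, fix_bottom_top, converged=False, message="non-positive Hill slope")

        # covariance from the Jacobian at the optimum
        dof = max(len(c) - n_params, 1)
        s2 = 2 * best.cost / dof
        JTJ = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = np.full((n_params, n_params), np.nan)
        return HillResults(self, best.x, cov, fix_bottom_top, converged=True, dof=dof, rss=float(2 * best.cost))

    # backwards-convenience alias used by the CLI
    def hill_fit(self, **kwargs) -> "HillResults":
        return self.fit(**kwargs)


class HillResults:
    """Results of a Hill fit: parameter estimates, uncertainties, diagnostics."""

    def __init__(self, model: HillModel, theta, cov, fixed: bool, converged: bool, message: str = "", dof: int = 0, rss: float = np.nan):
        self.model = model
        self.converged = converged
        self.message = message
        self.fixed_bottom_top = fixed
        self.dof = dof
        self.rss = rss
        self._theta = theta
        self.cov = cov
        if converged:
            self.log_ic50 = float(theta[0])
            self.ic50 = 10.0 ** self.log_ic50
            self.hill_slope = float(theta[1])
            self.bottom = 0.0 if fixed else float(theta[2])
            self.top = 1.0 if fixed else float(theta[3])
            se = np.sqrt(np.diag(cov)) if cov is not None else np.full(len(theta), np.nan)
            self.se_log_ic50 = float(se[0])
            self.se_hill_slope = float(se[1])
            # delta-method SE on the linear µM scale
            self.se_ic50 = float(self.ic50 * np.log(10) * se[0])
        else:
            self.ic50 = self.hill_slope = self.bottom = self.top = np.nan
            self.log_ic50 = self.se_log_ic50 = self.se_hill_slope = self.se_ic50 = np.nan

    @property
    def params(self) -> HillParams:
        if not self.converged:
            return HillParams(0.0, 1.0, np.nan, np.nan, converged=False)
        return HillParams(
            bottom=self.bottom, top=self.top, ic50=self.ic50, hill_slope=self.hill_slope,
            se_ic50=self.se_ic50, se_hill_slope=self.se_hill_slope, converged=self.converged,
        )

    def predict(self, c: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("fit did not converge")
        return hill_response(np.asarray(c, dtype=float), self.ic50, self.hill_slope, self.bottom, self.top)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """t-based confidence interval on log10(IC50), reported on the µM scale."""
        if not self.converged:
            raise RuntimeError("fit did not converge")
        tcrit = stats.t.ppf(1 - alpha / 2, self.dof)
        lo = self.log_ic50 - tcrit * self.se_log_ic50
        hi = self.log_ic50 + tcrit * self.se_log_ic50
        return {
            "ic50": (10.0**lo, 10.0**hi),
            "hill_slope": (
                self.hill_slope - tcrit * self.se_hill_slope,
                self.hill_slope + tcrit * self.se_hill_slope,
            ),
        }

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "message": self.message,
            "ic50_uM": self.ic50,
            "hill_slope": self.hill_slope,
            "bottom": self.bottom,
            "top": self.top,
            "se_ic50_uM": self.se_ic50,
            "se_hill_slope": self.se_hill_slope,
            "rss": self.rss,
            "dof": self.dof,
            "fixed_bottom_top": self.fixed_bottom_top,
        }

    def summary(self) -> str:
        if not self.converged:
            return f"Hill fit: NOT CONVERGED ({self.message})"
        ci = self.conf_int()
        lines = [
            "Hill concentration-response fit",
            "===============================",
            f"n points            {len(self.model.concentration)}",
            f"bottom/top          {self.bottom:.3f} / {self.top:.3f}"
            + ("  (fixed)" if self.fixed_bottom_top else ""),
            f"IC50 (uM)           {self.ic50:.4g}  (SE {self.se_ic50:.3g}, "
            f"95% CI {ci['ic50'][0]:.4g} - {ci['ic50'][1]:.4g})",
            f"Hill slope          {self.hill_slope:.4g}  (SE {self.se_hill_slope:.3g})",
            f"residual SS         {self.rss:.4g}  (dof {self.dof})",
        ]
        return "\n".join(lines)


def hill_fit(table: pd.DataFrame, fix_bottom_top: bool | None = None, conc: str = "concentration", resp: str = "response") -> HillResults:
    """Functional wrapper: fit a Hill curve to a dose–response table."""
    return HillModel.from_dataframe(table, conc=conc, resp=resp).fit(fix_bottom_top=fix_bottom_top)
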