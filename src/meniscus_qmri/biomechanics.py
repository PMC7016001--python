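"""Exponential hyperelastic modelling of unconfined-compression stress-strain data.

Meniscus, like other fibril-reinforced soft tissues, stiffens exponentially
under compression.  The two-parameter exponential model used here is

    sigma(eps) = c * (exp(b * eps) - 1)          [sigma in MPa, eps a fraction]

whose tangent stiffness ("Elastic Modulus") is the strain derivative

    EM(eps) = d sigma / d eps = c * b * exp(b * eps)

conventionally evaluated at 20 % and 80 % engineering strain to characterise
the low- and high-strain regimes.  The associated strain-energy form
Psi(eps) = c/(2b) * (exp(b*eps) - 1)**2 is provided as an alternative energy
evaluator; note that its second strain derivative differs from EM(eps) above,
so EM is defined from the stress model, not from Psi.

``b`` (dimensionless) sets the degree of nonlinearity and ``c`` (MPa) scales
the stress response.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "StressStrainCurve",
    "ExponentialCompressionModel",
    "HyperelasticFit",
    "fit_exponential",
    "elastic_modulus",
]

_DEFAULT_B_STARTS = (1.0, 3.0, 5.0, 8.0, 12.0)


@dataclass
class StressStrainCurve:
    """One sample's unconfined-compression curve (strain fraction, stress MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if np.any(self.strain < 0):
            raise ValueError("strain must be non-negative")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, strain_col: str = "strain",
        stress_col: str = "stress_MPa", sample_id: str | None = None,
    ) -> "StressStrainCurve":
        return cls(df[strain_col].to_numpy(), df[stress_col].to_numpy(), sample_id)


def elastic_modulus(b: float, c: float, strain) -> np.ndarray | float:
    """Tangent modulus EM(eps) = c * b * exp(b * eps) in MPa."""
    return c * b * np.exp(b * np.asarray(strain, dtype=float))


@dataclass
class HyperelasticFit:
    """Results of an exponential stress-strain fit.

    Carries the material parameters, their standard errors (Gauss-Newton
    covariance), the residual norm, and Elastic Modulus evaluations.
    """

    b: float
    c: float
    bse: tuple[float, float]
    residual_norm: float
    n_points: int
    sample_id: str | None = None
    tare_offset: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        return {"b": self.b, "c": self.c}

    def em(self, strain) -> np.ndarray | float:
        """Elastic Modulus EM(eps) = c*b*exp(b*eps) [MPa]."""
        return elastic_modulus(self.b, self.c, strain)

    @property
    def em_20(self) -> float:
        return float(self.em(0.2))

    @property
    def em_80(self) -> float:
        return float(self.em(0.8))

    def predict(self, strain) -> np.ndarray:
        """Fitted stress sigma(eps) = c*(exp(b*eps) - 1) [MPa]."""
        eps = np.asarray(strain, dtype=float)
        return self.c * (np.exp(self.b * eps) - 1.0)

    def strain_energy(self, strain) -> np.ndarray | float:
        """Strain energy Psi(eps) = c/(2b) * (exp(b*eps) - 1)**2 [MPa]."""
        eps = np.asarray(strain, dtype=float)
        return self.c / (2.0 * self.b) * (np.exp(self.b * eps) - 1.0) ** 2

    def summary(self) -> str:
        se_b, se_c = self.bse
        lines = [
            "Exponential stress-strain fit: sigma = c*(exp(b*eps) - 1)",
            "=" * 58,
            f"sample:         {self.sample_id or '-'}",
            f"n points:       {self.n_points}",
            f"b (nonlinearity) {self.b:12.5g}   (se {se_b:.3g})",
            f"c [MPa]          {self.c:12.5g}   (se {se_c:.3g})",
            f"residual norm    {self.residual_norm:12.5g} MPa",
            f"EM(20%) [MPa]    {self.em_20:12.5g}",
            f"EM(80%) [MPa]    {self.em_80:12.5g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot data (if retained) and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        eps = self.diagnostics.get("strain")
        sig = self.diagnostics.get("stress")
        if eps is not None:
            ax.plot(eps, sig, ".", ms=3, label="data")
            grid = np.linspace(eps.min(), eps.max(), 200)
        else:
            grid = np.linspace(0.0, 1.0, 200)
        ax.plot(grid, self.predict(grid), "-", label=f"fit b={self.b:.2f}, c={self.c:.3f}")
        ax.set_xlabel("strain [-]")
        ax.set_ylabel("stress [MPa]")
        ax.legend()
        return ax


class ExponentialCompressionModel:
    """Two-parameter exponential model for an unconfined-compression curve.

    Parameters
    ----------
    strain, stress : array-like
        Engineering strain (fraction, strictly increasing, >= 0) and stress
        in MPa.
    sample_id : str, optional
    tare : bool
        Remove the stress offset at the smallest strain before fitting so
        that sigma(0) = 0 (tare-load handling).  Default True.
    """

    def __init__(self, strain, stress, sample_id=None, tare=True):
        self.curve = StressStrainCurve(strain, stress, sample_id)
        if self.curve.strain.size < 5:
            raise ValueError("need at least 5 stress-strain points to fit")
        if self.curve.strain.max() < 0.5:
            warnings.warn(
                "stress-strain data span less than 50% strain; the fitted "
                "high-strain modulus extrapolates",
                stacklevel=2,
            )
        # warn on substantial (beyond noise-level) monotonicity violations
        span = float(np.ptp(self.curve.stress)) or 1.0
        drops = np.diff(self.curve.stress)
        if (drops.min(initial=0.0) < -0.1 * span) or np.any(
            self.curve.stress < -0.1 * span
        ):
            warnings.warn(
                "substantially non-monotone or negative stress data; fitting anyway",
                stacklevel=2,
            )
        self.tare = tare

    @classmethod
    def from_dataframe(cls, df, strain_col="strain", stress_col="stress_MPa", **kw):
        return cls(df[strain_col].to_numpy(), df[stress_col].to_numpy(), **kw)

    def fit(self, b_starts=_DEFAULT_B_STARTS) -> HyperelasticFit:
        """Least-squares fit with multi-start over the nonlinearity parameter."""
        eps = self.curve.strain
        sig = self.curve.stress.copy()
        offset = float(sig[0]) if self.tare else 0.0
        sig = sig - offset

        def resid(theta):
            b, c = theta
            return c * (np.exp(b * eps) - 1.0) - sig

        g = lambda b: np.exp(b * eps) - 1.0
        best = None
        for b0 in b_starts:
            gb = g(b0)
            denom = float(gb @ gb)
            c0 = float(sig @ gb) / denom if denom > 0 else 1.0
            c0 = max(c0, 1e-8)
            try:
                sol = least_squares(
                    resid,
                    x0=[b0, c0],
                    bounds=([1e-6, 1e-12], [60.0, np.inf]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.isfinite(best.cost):
            raise RuntimeError(
                f"exponential fit failed to converge from all starts "
                f"(sample {self.curve.sample_id})"
            )
        b, c = best.x
        # Gauss-Newton covariance for standard errors
        J = best.jac
        dof = max(eps.size - 2, 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            bse = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
        except np.linalg.LinAlgError:
            bse = (np.nan, np.nan)
        return HyperelasticFit(
            b=float(b),
            c=float(c),
            bse=bse,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            n_points=int(eps.size),
            sample_id=self.curve.sample_id,
            tare_offset=offset,
            diagnostics={"strain": eps, "stress": sig},
        )


def fit_exponential(curve_or_strain, stress=None, sample_id=None, tare=True) -> HyperelasticFit:
    """Functional wrapper: fit sigma = c*(exp(b*eps)-1) to a curve.

    Accepts either a :class:`StressStrainCurve` or ``(strain, stress)`` arrays.
    """
    if isinstance(curve_or_strain, StressStrainCurve):
        curve = curve_or_strain
        model = ExponentialCompressionModel(
            curve.strain, curve.stress, sample_id=curve.sample_id, tare=tare
        )
    else:
        model = ExponentialCompressionModel(
            curve_or_strain, stress, sample_id=sample_id, tare=tare
        )
    return model.fit()
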