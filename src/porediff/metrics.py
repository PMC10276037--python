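"""Scalar transport analysis: tortuosity, Archie's law, error metrics.

The diffusive tortuosity of a medium is ``lambda = D0 / D``.  Archie's law
relates tortuosity to porosity through an exponent ``n``:
``lambda**2 = phi**(1 - n)``.  Taking the effective diffusion coefficient as
the reciprocal of the tortuosity squared (in units of D0) gives the power law
``D = phi**(n - 1)``, which is fitted here in log-log space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Split",
    "SampleRecord",
    "ArchieFit",
    "tortuosity",
    "fit_archie",
    "chibar2",
    "field_error_stats",
]


class Split(str, enum.Enum):
    TRAIN = "train"
    VAL = "val"


@dataclass
class SampleRecord:
    """A labelled (porosity, effective diffusion) pair for one sample."""

    sample_id: str
    phi: float
    D: float
    split: Split = Split.TRAIN

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 1.0:
            raise ValueError(f"phi must lie in (0, 1], got {self.phi}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")


@dataclass
class ArchieFit:
    """Result of fitting D = phi**(n-1)."""

    n: float
    residual: float
    n_records: int


def tortuosity(D0: float, D: float) -> float:
    """Diffusive tortuosity lambda = D0 / D (>= 1 for hindered transport).

    A blocked medium (D = 0) has infinite tortuosity; ``inf`` is returned.
    """
    if D < 0 or D0 <= 0:
        raise ValueError("require D >= 0 and D0 > 0")
    if D == 0.0:
        return float("inf")
    return D0 / D


def fit_archie(records: list[SampleRecord]) -> ArchieFit:
    """Least-squares fit of the Archie exponent on (phi, D) records.

    Regresses ``log D`` on ``log phi`` with slope ``n - 1`` (unweighted).
    Blocked records (D = 0) have no logarithm and are excluded.  Raises if
    the porosities do not vary (ill-conditioned fit).
    """
    usable = [r for r in records if r.D > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 records with D > 0")
    phi = np.array([r.phi for r in usable])
    D = np.array([r.D for r in usable])
    x = np.log(phi)
    if np.ptp(x) < 1e-12:
        raise ValueError("all records at one porosity: ill-conditioned fit")
    y = np.log(D)
    coeffs, res, *_ = np.polyfit(x, y, 1, full=True)
    slope = float(coeffs[0])
    residual = float(res[0]) if len(res) else 0.0
    return ArchieFit(n=slope + 1.0, residual=residual, n_records=len(usable))


def chibar2(
    pred: np.ndarray, true: np.ndarray, sigma: np.ndarray
) -> float:
    """Uncertainty-weighted mean squared error over (phi, D) pairs.

    ``(1/N) sum_i [ (phi_p - phi_t)^2 / dphi^2 + (D_p - D_t)^2 / dD^2 ]``
    with per-sample 1-sigma uncertainties from MC dropout.  Inputs are
    ``(N, 2)`` arrays.
    """
    pred = np.atleast_2d(np.asarray(pred, float))
    true = np.atleast_2d(np.asarray(true, float))
    sigma = np.atleast_2d(np.asarray(sigma, float))
    if not (pred.shape == true.shape == sigma.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, true {true.shape}, sigma {sigma.shape}"
        )
    if np.any(sigma <= 0):
        raise ValueError("sigmas must be strictly positive")
    return float((((pred - true) / sigma) ** 2).sum(axis=1).mean())


def field_error_stats(
    true_field: np.ndarray,
    pred_field: np.ndarray,
    fluid_mask: np.ndarray | None = None,
    uncertainty: np.ndarray | None = None,
    bins: int = 50,
) -> dict:
    """Node-wise reconstruction error summary for a concentration map.

    Returns the absolute-difference map, its mean over *all* nodes (the
    headline metric), the fluid-only mean when a mask is given (diagnostic),
    and a histogram; the same summaries are produced for an uncertainty map
    when provided.
    """
    true_field = np.asarray(true_field, float)
    pred_field = np.asarray(pred_field, float)
    if true_field.shape != pred_field.shape:
        raise ValueError(
            f"shape mismatch: {true_field.shape} vs {pred_field.shape}"
        )
    abs_err = np.abs(true_field - pred_field)
    # explicit range guards the degenerate constant-error case
    hist, edges = np.histogram(
        abs_err, bins=bins, range=(0.0, max(float(abs_err.max()), 1e-9))
    )
    out = {
        "abs_error_map": abs_err,
        "mean_abs_error": float(abs_err.mean()),
        "hist": hist,
        "hist_edges": edges,
    }
    if fluid_mask is not None:
        fluid_mask = np.asarray(fluid_mask, bool)
        if fluid_mask.shape != true_field.shape:
            raise ValueError("fluid_mask shape mismatch")
        out["mean_abs_error_fluid"] = (
            float(abs_err[fluid_mask].mean()) if fluid_mask.any() else 0.0
        )
    if uncertainty is not None:
        uncertainty = np.asarray(uncertainty, float)
        if uncertainty.shape != true_field.shape:
            raise ValueError("uncertainty shape mismatch")
        u_hist, u_edges = np.histogram(
            uncertainty, bins=bins,
            range=(0.0, max(float(uncertainty.max()), 1e-9)),
        )
        out["mean_uncertainty"] = float(uncertainty.mean())
        out["uncertainty_hist"] = u_hist
        out["uncertainty_hist_edges"] = u_edges
    return out
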