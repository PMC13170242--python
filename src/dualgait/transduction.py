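"""Optical strain transduction model and sensor calibration metrics.

A stretchable polymer waveguide between two plastic optical fiber terminals
attenuates transmitted light as it is strained.  The transmitted intensity
follows a Beer-Lambert form with a strain-proportional loss term,

    I(eps) = I0 * eta1 * eta2 * exp(-(alpha0 + k_s * eps) * L),

where ``eps`` is tensile strain (as a fraction), ``I0`` the launched optical
power, ``eta1``/``eta2`` the input/output coupling efficiencies, ``alpha0``
the intrinsic attenuation (per mm), ``k_s`` the strain-extinction coefficient
(per mm per unit strain) and ``L`` the effective sensing length (mm).  Taking
logs gives the linear form ``ln I = C - k_s*L*eps`` with
``C = ln(I0*eta1*eta2) - alpha0*L``; at large strains a second-order
extension ``ln I = C - a1*eps - a2*eps**2`` accommodates coupling and
scattering nonlinearities.

Calibration follows a staircase protocol: cyclic tensile loading 0..100%
strain in 10% increments, loading then unloading, repeated three times.  The
module fits sensitivity (mV per % strain) in the voltage domain, recovers
``k_s*L`` in the log domain, and computes the maximum hysteresis error

    H% = max_eps |V_load(eps) - V_unload(eps)| / V_FS * 100,

with ``V_FS`` the full-scale output span of the mean loading branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TransductionParams",
    "CalibrationCurve",
    "CalibrationFit",
    "forward_intensity",
    "fit_calibration",
    "hysteresis_error",
    "baseline_drift_percent",
]


@dataclass(frozen=True)
class TransductionParams:
    """Physical parameters of the optical strain model.

    Strain is handled internally as a fraction (0.2 == 20% strain); only
    reports and file formats use percent.
    """

    incident_power: float = 1.0          # I0, arbitrary optical units
    coupling_in: float = 1.0             # eta1, (0, 1]
    coupling_out: float = 1.0            # eta2, (0, 1]
    intrinsic_loss: float = 0.0          # alpha0, per mm
    extinction: float = 0.0              # k_s, per mm per unit strain
    effective_length: float = 1.0        # L, mm
    quad_a1: Optional[float] = None      # per unit strain (order-2 model)
    quad_a2: Optional[float] = None      # per unit strain squared
    strain_window: float = 1.0           # max operational strain (fraction)

    def __post_init__(self) -> None:
        if self.incident_power <= 0:
            raise ValueError("incident_power must be > 0")
        if self.effective_length <= 0:
            raise ValueError("effective_length must be > 0")
        if not (0 < self.coupling_in <= 1 and 0 < self.coupling_out <= 1):
            raise ValueError("coupling efficiencies must lie in (0, 1]")
        if self.intrinsic_loss < 0 or self.extinction < 0:
            raise ValueError("loss coefficients must be >= 0")

    @property
    def log_intercept(self) -> float:
        """C = ln(I0*eta1*eta2) - alpha0*L."""
        return (
            np.log(self.incident_power * self.coupling_in * self.coupling_out)
            - self.intrinsic_loss * self.effective_length
        )


@dataclass
class CalibrationCurve:
    """Staircase calibration data: output (mV) on a shared strain grid.

    ``loading_mV`` and ``unloading_mV`` have shape ``(replicates, n_grid)``.
    """

    strain_pct: np.ndarray
    loading_mV: np.ndarray
    unloading_mV: np.ndarray

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.loading_mV = np.atleast_2d(np.asarray(self.loading_mV, dtype=float))
        self.unloading_mV = np.atleast_2d(np.asarray(self.unloading_mV, dtype=float))
        if self.strain_pct.ndim != 1 or np.any(np.diff(self.strain_pct) < 0):
            raise ValueError("strain_pct must be a 1-D ascending grid")
        n = self.strain_pct.size
        if self.loading_mV.shape[1] != n or self.unloading_mV.shape[1] != n:
            raise ValueError("branch arrays must match the strain grid length")
        if self.loading_mV.shape != self.unloading_mV.shape:
            raise ValueError("loading and unloading branches must be congruent")

    @property
    def replicate_count(self) -> int:
        return self.loading_mV.shape[0]

    def mean_loading(self) -> np.ndarray:
        return self.loading_mV.mean(axis=0)

    def mean_unloading(self) -> np.ndarray:
        return self.unloading_mV.mean(axis=0)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for branch, arr in (("load", self.loading_mV), ("unload", self.unloading_mV)):
            for rep in range(arr.shape[0]):
                for s, v in zip(self.strain_pct, arr[rep]):
                    rows.append((s, branch, rep, v))
        pd.DataFrame(
            rows, columns=["strain_pct", "branch", "replicate", "output_mV"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        grid = np.sort(df["strain_pct"].unique())

        def branch(name: str) -> np.ndarray:
            sub = df[df["branch"] == name]
            piv = sub.pivot_table(
                index="replicate", columns="strain_pct", values="output_mV"
            )
            return piv.reindex(columns=grid).to_numpy()

        return cls(grid, branch("load"), branch("unload"))


@dataclass
class CalibrationFit:
    """Result of a calibration fit plus hysteresis metrics."""

    sensitivity: float           # |slope|, mV per % strain (voltage domain)
    intercept: float             # mV at 0% strain
    r_squared: float
    hysteresis_max: float        # %
    hysteresis_strain: float     # % strain where the max gap occurs
    fit_order: int
    degenerate: bool = False
    log_slope: Optional[float] = None   # k_s*L estimate (per unit strain)
    log_slope_se: Optional[float] = None
    coefficients: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sensitivity_mV_per_pct": self.sensitivity,
            "intercept_mV": self.intercept,
            "r_squared": self.r_squared,
            "hysteresis_max_pct": self.hysteresis_max,
            "hysteresis_strain_pct": self.hysteresis_strain,
            "fit_order": self.fit_order,
            "degenerate": self.degenerate,
            "log_slope": self.log_slope,
            "log_slope_se": self.log_slope_se,
            "coefficients": list(self.coefficients),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def forward_intensity(
    params: TransductionParams, strain: float | np.ndarray, order: int = 1
) -> float | np.ndarray:
    """Transmitted intensity at tensile strain ``strain`` (a fraction).

    Order 1 evaluates the Beer-Lambert form with strain-proportional loss;
    order 2 evaluates ``exp(C - a1*eps - a2*eps**2)`` and requires
    ``quad_a1``/``quad_a2`` to be set.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < 0) or np.any(eps > params.strain_window):
        raise ValueError(
            f"strain must lie in [0, {params.strain_window}] (fractional units)"
        )
    if order == 1:
        alpha = params.intrinsic_loss + params.extinction * eps
        out = (
            params.incident_power
            * params.coupling_in
            * params.coupling_out
            * np.exp(-alpha * params.effective_length)
        )
    elif order == 2:
        if params.quad_a1 is None or params.quad_a2 is None:
            raise ValueError("order-2 model requires quad_a1 and quad_a2")
        out = np.exp(
            params.log_intercept - params.quad_a1 * eps - params.quad_a2 * eps**2
        )
    else:
        raise ValueError("order must be 1 or 2")
    return out if np.ndim(strain) else float(out)


def hysteresis_error(curve: CalibrationCurve) -> tuple[float, float]:
    """Maximum hysteresis error H% and the strain (in %) where it occurs.

    Branches are averaged pointwise over replicates before the gap scan.
    The full-scale span is |V_load(max grid) - V_load(min grid)| of the mean
    loading branch.  Ties break toward the lowest strain.
    """
    load = curve.mean_loading()
    unload = curve.mean_unloading()
    v_fs = abs(load[-1] - load[0])
    if v_fs == 0:
        raise ZeroDivisionError(
            "full-scale span is zero; hysteresis error is undefined"
        )
    gaps = np.abs(load - unload)
    idx = int(np.argmax(gaps))  # argmax returns the first (lowest-strain) max
    h_max = float(gaps[idx] / v_fs * 100.0)
    return h_max, float(curve.strain_pct[idx])


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, bool]:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0, True
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot, False


def fit_calibration(
    curve: CalibrationCurve, order: int = 1, domain: str = "voltage"
) -> CalibrationFit:
    """Least-squares fit of the mean loading branch against strain.

    ``domain='voltage'`` fits output mV against % strain; the reported
    sensitivity is the absolute slope (mV/%).  ``domain='log'`` fits
    ln(output) against fractional strain so that the slope magnitude of the
    order-1 fit estimates ``k_s * L`` (the demodulator is assumed affine in
    intensity with negligible offset for the log fit).
    """
    x_pct = curve.strain_pct
    if np.unique(x_pct).size < max(3, order + 2):
        if np.unique(x_pct).size <= 1:
            raise ValueError("degenerate strain grid: all strains equal")
        raise ValueError(
            f"order-{order} fit needs at least {max(3, order + 2)} distinct strains"
        )
    y = curve.mean_loading()

    log_slope = log_slope_se = None
    if domain == "log":
        if np.any(y <= 0):
            raise ValueError("log-domain fit requires strictly positive outputs")
        x = x_pct / 100.0  # fractional strain so slope = k_s*L
        yy = np.log(y)
    elif domain == "voltage":
        x = x_pct
        yy = y
    else:
        raise ValueError("domain must be 'voltage' or 'log'")

    coeffs = np.polyfit(x, yy, deg=order)
    y_hat = np.polyval(coeffs, x)
    r2, degenerate = _r_squared(yy, y_hat)
    slope = float(coeffs[-2])  # linear coefficient

    if domain == "log":
        log_slope = abs(slope)
        resid = yy - y_hat
        dof = max(x.size - (order + 1), 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        log_slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
        sensitivity = abs(slope)  # per unit strain in log units
    else:
        sensitivity = abs(slope)

    try:
        h_max, h_strain = hysteresis_error(curve)
    except ZeroDivisionError:
        if not degenerate:
            raise
        h_max, h_strain = 0.0, float(curve.strain_pct[0])
    return CalibrationFit(
        sensitivity=sensitivity,
        intercept=float(coeffs[-1]),
        r_squared=max(r2, 0.0) if not degenerate else 0.0,
        hysteresis_max=h_max,
        hysteresis_strain=h_strain,
        fit_order=order,
        degenerate=degenerate,
        log_slope=log_slope,
        log_slope_se=log_slope_se,
        coefficients=list(np.asarray(coeffs, dtype=float)),
    )


def baseline_drift_percent(initial_mV: float, max_fluctuation_mV: float) -> float:
    """Baseline drift as a percentage of the initial output, 2 significant figures.

    Used for long-exposure photo-aging stability: the maximum baseline
    fluctuation relative to the initial 0%-strain output.
    """
    if initial_mV <= 0:
        raise ValueError("initial output must be positive")
    if max_fluctuation_mV < 0:
        raise ValueError("fluctuation must be >= 0")
    pct = 100.0 * max_fluctuation_mV / initial_mV
    if pct == 0.0:
        return 0.0
    return float(f"{pct:.2g}")
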