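"""Synthetic HPLC activity-assay data for the ASN mechanism.

Emulates the measurement chain of an o-phthalaldehyde/fluorescence HPLC
enzyme assay: the mechanism is simulated from assay initial conditions,
asparagine and glutamate are sampled at the assay time points (1.5, 2.5,
3.5, 5, 15, 25 and 35 min by default, two replicates), true concentrations
are mapped to peak areas through a linear calibration, multiplicative
Gaussian noise is applied per replicate measurement, and areas are converted
back to concentrations through a freshly fitted standard curve (standards at
0, 5, 10, 15 and 20 nmol) — exactly the inversion applied to real
chromatograms.

The generator works in abstract model concentration units throughout and
treats the calibration as a linear map on whatever unit the dataset declares
(recorded in metadata), since peak area per amount is instrument-specific.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import asn_model, simulate
from .netcore import ReactionNetwork

__all__ = [
    "STANDARD_CONCENTRATIONS",
    "DEFAULT_TIME_POINTS_S",
    "CalibrationCurve",
    "AreaConversion",
    "AssayDataset",
    "simulate_calibration",
    "fit_calibration",
    "area_to_concentration",
    "generate_assay_dataset",
]

# calibration standards, nmol of amino acid per injection
STANDARD_CONCENTRATIONS = np.array([0.0, 5.0, 10.0, 15.0, 20.0])

# assay sampling times: 1.5, 2.5, 3.5, 5, 15, 25, 35 min in seconds
DEFAULT_TIME_POINTS_S = np.array([90.0, 150.0, 210.0, 300.0, 900.0, 1500.0, 2100.0])

DEFAULT_N_REPLICATES = 2
DEFAULT_SLOPE = 100.0  # area per concentration unit
DEFAULT_INTERCEPT = 0.0
OBSERVED_SPECIES = ("Asn", "Glu")


class UnusableCurveError(ValueError):
    """Calibration slope is not positive; areas cannot be inverted."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary-least-squares line mapping concentration to peak area."""

    slope: float
    intercept: float
    residual_se: float
    standards: pd.DataFrame  # columns: concentration, area


class AreaConversion(NamedTuple):
    concentration: float
    below_range: bool


@dataclass
class AssayDataset:
    """Replicate Asn/Glu measurements at assay time points.

    ``measurements`` has one row per (replicate, time, species) with both the
    raw peak area and the back-calculated concentration.  ``metadata`` records
    the generating parameters, noise level, seed and unit label when the
    dataset is synthetic.
    """

    enzyme: str
    time_points: np.ndarray
    measurements: pd.DataFrame  # columns: replicate, time_s, species, area, concentration
    n_replicates: int
    metadata: dict = field(default_factory=dict)

    def observed(self, species: str) -> pd.DataFrame:
        return self.measurements[self.measurements["species"] == species]

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = self.measurements.copy()
        df.insert(0, "enzyme", self.enzyme)
        df.to_csv(path, index=False)
        if sidecar is not None:
            meta = dict(self.metadata)
            meta["enzyme"] = self.enzyme
            meta["n_replicates"] = self.n_replicates
            meta["time_points_s"] = list(map(float, self.time_points))
            Path(sidecar).write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "AssayDataset":
        df = pd.read_csv(path)
        required = {"enzyme", "replicate", "time_s", "species", "concentration"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV is missing columns {sorted(missing)}")
        bad = df[df["concentration"] < 0]
        if not bad.empty:
            raise ValueError(
                f"negative concentration at row {int(bad.index[0])}"
            )
        enzymes = df["enzyme"].unique()
        if len(enzymes) != 1:
            raise ValueError("dataset CSV must contain exactly one enzyme")
        meta = {}
        if sidecar is not None and Path(sidecar).exists():
            meta = json.loads(Path(sidecar).read_text())
        return cls(
            enzyme=str(enzymes[0]),
            time_points=np.sort(df["time_s"].unique().astype(float)),
            measurements=df.drop(columns=["enzyme"]),
            n_replicates=int(df["replicate"].nunique()),
            metadata=meta,
        )


def simulate_calibration(
    true_slope: float = DEFAULT_SLOPE,
    true_intercept: float = DEFAULT_INTERCEPT,
    noise_cv: float = 0.0,
    seed: int | None = None,
    concentrations: Sequence[float] = STANDARD_CONCENTRATIONS,
) -> pd.DataFrame:
    """Generate a standards table: area = b0 + b1*conc, noised multiplicatively."""
    if true_slope <= 0:
        raise UnusableCurveError("true_slope must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    area = true_intercept + true_slope * conc
    area = area * (1.0 + rng.normal(0.0, noise_cv, size=conc.shape))
    return pd.DataFrame({"concentration": conc, "area": area})


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Fit area on concentration by ordinary least squares."""
    conc = np.asarray(standards["concentration"], dtype=float)
    area = np.asarray(standards["area"], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("calibration requires at least two distinct concentrations")
    res = stats.linregress(conc, area)
    fitted = res.intercept + res.slope * conc
    dof = max(len(conc) - 2, 1)
    resid_se = float(np.sqrt(np.sum((area - fitted) ** 2) / dof))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_se=resid_se,
        standards=standards.copy(),
    )


def area_to_concentration(curve: CalibrationCurve, area: float) -> AreaConversion:
    """Invert the standard curve; negative results clip to 0 with a flag."""
    if curve.slope <= 0:
        raise UnusableCurveError("calibration slope must be positive to invert")
    conc = (float(area) - curve.intercept) / curve.slope
    if conc < 0:
        return AreaConversion(0.0, True)
    return AreaConversion(conc, False)


def generate_assay_dataset(
    enzyme: str,
    params: asn_model.RateParams | Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    time_points: Sequence[float] | None = None,
    *,
    net: ReactionNetwork | None = None,
    initial_overrides: Mapping[str, float] | None = None,
    calibration_slope: float = DEFAULT_SLOPE,
    calibration_intercept: float = DEFAULT_INTERCEPT,
) -> AssayDataset:
    """Simulate the assay and push samples through the full measurement chain.

    Steps: integrate the mechanism from the enzyme's default initial state;
    sample Asn and Glu at the assay time points; map to peak areas through
    the true calibration line; apply per-measurement multiplicative Gaussian
    noise; fit a fresh standard curve from (equally noisy) standards and
    invert it to recover concentrations.  With ``noise_cv=0`` the chain is
    the identity and the dataset equals the simulated truth.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    profile = asn_model.enzyme_profile(enzyme)
    if params is None:
        params = profile.params
    pdict = params.as_dict() if isinstance(params, asn_model.RateParams) else dict(params)

    tp = np.asarray(
        DEFAULT_TIME_POINTS_S if time_points is None else time_points, dtype=float
    )
    tp = np.sort(tp)
    if net is None:
        net = asn_model.build_asn_network()
    state0 = asn_model.default_initial_state(enzyme, initial_overrides)

    traj = simulate.integrate(net, pdict, state0, times=tp)
    idx = np.searchsorted(traj.time, tp)
    truth = {sp: traj[sp][idx] for sp in OBSERVED_SPECIES}

    rng = np.random.default_rng(seed)
    # fresh standards measured with the same noise level, as in a real run
    standards = simulate_calibration(
        calibration_slope,
        calibration_intercept,
        noise_cv,
        seed=rng.integers(2**31),
    )
    curve = fit_calibration(standards)

    rows = []
    for rep in range(1, n_replicates + 1):
        for sp in OBSERVED_SPECIES:
            true_area = calibration_intercept + calibration_slope * truth[sp]
            noisy = true_area * (1.0 + rng.normal(0.0, noise_cv, size=tp.shape))
            for t, a in zip(tp, noisy):
                conv = area_to_concentration(curve, a)
                rows.append(
                    {
                        "replicate": rep,
                        "time_s": float(t),
                        "species": sp,
                        "area": float(a),
                        "concentration": conv.concentration,
                    }
                )
    measurements = pd.DataFrame(rows)
    metadata = {
        "synthetic": True,
        "true_params": pdict,
        "noise_cv": noise_cv,
        "seed": seed,
        "unit": "model c.u. (mM-equivalent)",
        "calibration_true_slope": calibration_slope,
        "calibration_true_intercept": calibration_intercept,
        "fitted_calibration": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "residual_se": curve.residual_se,
        },
        "initial_state": state0,
    }
    return AssayDataset(
        enzyme=enzyme,
        time_points=tp,
        measurements=measurements,
        n_replicates=n_replicates,
        metadata=metadata,
    )
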