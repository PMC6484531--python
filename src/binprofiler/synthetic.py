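"""Synthetic multi-plate single-cell screens with planted ground truth.

The generator emulates the per-cell feature tables produced by image-analysis
pipelines on compound screens: plates carrying many vehicle-control (DMSO)
wells and treated wells, a few hundred cells per well, and parameters of four
kinds —

* ``stable_uninformative``: i.i.d. draws from the plate baseline everywhere;
* ``stable_informative``: baseline in controls, shifted in treated wells of
  the classes whose signature contains them, either by translating the
  population mean or by a bimodal split that moves half the cells up and half
  down (leaving the well average nearly unchanged while filling the extreme
  bins);
* ``noisy``: an independent per-well location offset (well-to-well drift)
  on top of the baseline, in control and treated wells alike;
* ``degenerate``: a single constant for >= 99% of cells (e.g. nuclei count).

Effects are expressed in baseline-sd units and applied on the latent standard
scale; each plate x parameter then gets its own location and scale (and
optionally a log-normal warp), which quantile binning is invariant to.  All
randomness flows from one seed through per-(plate, well) child streams, so a
given seed regenerates byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    CONCENTRATION,
    DEFAULT_CONTROL,
    MOA,
    PLATE,
    TREATMENT,
    WELL,
    CellFeatureTable,
)

ROLE_STABLE = "stable_uninformative"
ROLE_INFORMATIVE = "stable_informative"
ROLE_NOISY = "noisy"
ROLE_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic screen.

    Defaults describe a small two-plate screen with 20 control wells per
    plate, ~500 cells per well (Poisson-dispersed), 100 parameters of which
    20 drift from well to well (sd 0.5 baseline units) and 2 are degenerate,
    and three mode-of-action classes of three compounds, each class shifting
    its own disjoint trio of parameters by two baseline sds (half of them as
    bimodal splits).
    """

    seed: int = 0
    plates: int = 2
    dmso_wells_per_plate: int = 20
    cells_per_well: int = 500
    n_parameters: int = 100
    n_noisy: int = 20
    n_degenerate: int = 2
    moa_classes: int = 3
    compounds_per_class: int = 3
    replicates: int = 2
    signature_size: int = 3
    effect_size: float = 2.0
    bimodal_fraction: float = 0.5
    noise_drift_sd: float = 0.5
    degenerate_fraction: float = 0.995
    baseline: str = "normal"  # or "lognormal"
    control: str = DEFAULT_CONTROL

    def __post_init__(self) -> None:
        n_informative = self.moa_classes * self.signature_size
        if self.n_noisy + self.n_degenerate + n_informative > self.n_parameters:
            raise ValueError("parameter roles exceed n_parameters")
        if self.dmso_wells_per_plate < 2:
            raise ValueError("need >= 2 control wells per plate")
        if self.replicates > self.plates:
            raise ValueError("replicates cannot exceed plates")
        if not (0.0 <= self.bimodal_fraction <= 1.0):
            raise ValueError("bimodal_fraction must be in [0, 1]")
        if self.baseline not in ("normal", "lognormal"):
            raise ValueError("baseline must be 'normal' or 'lognormal'")

    @property
    def n_compounds(self) -> int:
        return self.moa_classes * self.compounds_per_class


@dataclass
class GroundTruth:
    """Planted roles and class signatures of a generated screen."""

    parameter_roles: dict[str, str]
    class_signatures: dict[str, list[dict]]

    def parameters_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, r in self.parameter_roles.items() if r == role))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _design(config: SyntheticConfig) -> tuple[GroundTruth, dict]:
    """Deterministic screen design: roles, signatures, per-plate baselines."""
    rng = np.random.default_rng([config.seed, 0])
    params = [f"p{i:03d}" for i in range(config.n_parameters)]
    order = list(rng.permutation(config.n_parameters))
    roles = {p: ROLE_STABLE for p in params}
    cursor = 0
    for _ in range(config.n_noisy):
        roles[params[order[cursor]]] = ROLE_NOISY
        cursor += 1
    for _ in range(config.n_degenerate):
        roles[params[order[cursor]]] = ROLE_DEGENERATE
        cursor += 1
    informative: list[str] = []
    for _ in range(config.moa_classes * config.signature_size):
        p = params[order[cursor]]
        roles[p] = ROLE_INFORMATIVE
        informative.append(p)
        cursor += 1

    signatures: dict[str, list[dict]] = {}
    n_bimodal = int(round(config.bimodal_fraction * config.signature_size))
    for c in range(config.moa_classes):
        sig_params = informative[c * config.signature_size : (c + 1) * config.signature_size]
        sig = []
        for j, p in enumerate(sig_params):
            sig.append(
                {
                    "parameter": p,
                    "direction": int(rng.choice([-1, 1])),
                    "kind": "bimodal" if j < n_bimodal else "translate",
                }
            )
        signatures[f"moa_{c}"] = sig
    truth = GroundTruth(parameter_roles=roles, class_signatures=signatures)

    baselines = {}
    for plate_idx in range(config.plates):
        prng = np.random.default_rng([config.seed, 1, plate_idx])
        baselines[plate_idx] = {
            "loc": prng.normal(0.0, 2.0, size=config.n_parameters),
            "scale": prng.uniform(0.5, 2.0, size=config.n_parameters),
        }
    return truth, baselines


def _well_cells(
    config: SyntheticConfig,
    truth: GroundTruth,
    baselines: dict,
    plate_idx: int,
    well_idx: int,
    signature: list[dict] | None,
) -> np.ndarray:
    """Latent-scale draw for one well, warped to the plate baseline."""
    rng = np.random.default_rng([config.seed, 2, plate_idx, well_idx])
    n = max(10, int(rng.poisson(config.cells_per_well)))
    params = sorted(truth.parameter_roles)
    P = len(params)
    z = rng.standard_normal((n, P))
    roles = truth.parameter_roles
    for j, p in enumerate(params):
        if roles[p] == ROLE_NOISY:
            z[:, j] += rng.normal(0.0, config.noise_drift_sd)
    if signature:
        col = {p: j for j, p in enumerate(params)}
        for entry in signature:
            j = col[entry["parameter"]]
            if entry["kind"] == "translate":
                z[:, j] += entry["direction"] * config.effect_size
            else:  # balanced bimodal split: well mean ~unchanged
                half = n // 2
                z[:half, j] += config.effect_size
                z[half:, j] -= config.effect_size
    loc = baselines[plate_idx]["loc"]
    scale = baselines[plate_idx]["scale"]
    if config.baseline == "lognormal":
        values = loc[None, :] + scale[None, :] * np.exp(0.5 * z)
    else:
        values = loc[None, :] + scale[None, :] * z
    for j, p in enumerate(params):
        if roles[p] == ROLE_DEGENERATE:
            rare = rng.random(n) >= config.degenerate_fraction
            values[:, j] = loc[j]
            values[rare, j] = loc[j] + scale[j] * (1.0 + np.abs(z[rare, j]))
    return values


def generate_screen(config: SyntheticConfig) -> tuple[CellFeatureTable, GroundTruth]:
    """Generate a full synthetic screen and its ground truth.

    Each plate carries ``dmso_wells_per_plate`` control wells; every compound
    appears once per plate on the first ``replicates`` plates.  Fully
    reproducible from ``config.seed``.
    """
    truth, baselines = _design(config)
    params = sorted(truth.parameter_roles)
    frames: list[pd.DataFrame] = []
    for plate_idx in range(config.plates):
        plate_id = f"plate{plate_idx + 1:02d}"
        layout: list[tuple[str, str, object]] = []  # (well, treatment, moa)
        for w in range(config.dmso_wells_per_plate):
            layout.append((f"w{w + 1:02d}", config.control, None))
        if plate_idx < config.replicates:
            w = config.dmso_wells_per_plate
            for c in range(config.moa_classes):
                for i in range(config.compounds_per_class):
                    layout.append((f"w{w + 1:02d}", f"cpd_{c}_{i}", f"moa_{c}"))
                    w += 1
        for well_idx, (well_id, treatment, moa) in enumerate(layout):
            sig = truth.class_signatures.get(moa) if moa is not None else None
            values = _well_cells(config, truth, baselines, plate_idx, well_idx, sig)
            df = pd.DataFrame(values, columns=params)
            df.insert(0, PLATE, plate_id)
            df.insert(1, WELL, well_id)
            df.insert(2, TREATMENT, treatment)
            df.insert(3, MOA, moa)
            df.insert(4, CONCENTRATION, 1.0)
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    table = CellFeatureTable(data=data, features=tuple(params), control=config.control)
    return table, truth


# ---------------------------------------------------------------------------
# Worked example: a tiny fixed screen with hand-checkable binning outputs
# ---------------------------------------------------------------------------


def generate_worked_example() -> tuple[CellFeatureTable, dict]:
    """A tiny deterministic screen with hand-verifiable binning statistics.

    Two identical plates of 8 wells (5 DMSO + 3 treated), 100 cells per well,
    6 parameters.  The ``uniform`` parameter's pooled control values on each
    plate are exactly 1..500, dealt so that four control wells hold counts
    (15, 18, 22, 22, 23) across the five bins and the fifth — a planted
    drift well — holds (40, 28, 12, 12, 8).  The returned ``expected`` dict
    freezes the hand computations: pooled per-bin occupancy 100, drift-well
    chi-square 736/20 = 36.8, regular-well chi-square 46/20 = 2.3 (df 4).
    """
    rng = np.random.default_rng(20210612)
    n_cells, n_dmso, n_treated = 100, 5, 3
    drift_counts = np.array([40, 28, 12, 12, 8])
    regular_counts = (np.array([100] * 5) - drift_counts) // 4  # (15,18,22,22,23)

    # Deal 1..500 into wells with the prescribed per-bin counts.  Bin b holds
    # values 100*b+1 .. 100*(b+1) (edges fall strictly inside each hundred).
    uniform_wells: list[list[float]] = [[] for _ in range(n_dmso)]
    for b in range(5):
        vals = list(range(100 * b + 1, 100 * b + 101))
        take = drift_counts[b]
        uniform_wells[4].extend(vals[:take])
        rest = vals[take:]
        per = regular_counts[b]
        for w in range(4):
            uniform_wells[w].extend(rest[w * per : (w + 1) * per])

    frames = []
    for plate_idx in range(2):
        plate = f"plate{plate_idx + 1:02d}"
        for w in range(n_dmso + n_treated):
            treated = w >= n_dmso
            well = f"w{w + 1:02d}"
            base = rng.standard_normal((n_cells, 1))
            shifted = base + (2.0 if treated else 0.0)
            bimodal = rng.standard_normal((n_cells, 1))
            if treated:
                bimodal[: n_cells // 2] += 2.0
                bimodal[n_cells // 2 :] -= 2.0
            drift = rng.standard_normal((n_cells, 1)) + (
                rng.normal(0.0, 0.8) if w in (1, 3) else 0.0
            )
            degen = np.ones((n_cells, 1))
            degen[rng.random(n_cells) >= 0.99] = 2.0
            if treated:
                uniform = np.linspace(60.0, 440.0, n_cells)[:, None]
            else:
                uniform = np.array(uniform_wells[w], dtype=float)[:, None]
            constant = np.full((n_cells, 1), 7.0)
            df = pd.DataFrame(
                np.hstack([uniform, shifted, bimodal, drift, degen, constant]),
                columns=["uniform", "shifted", "bimodal", "drift", "degenerate", "constant"],
            )
            df.insert(0, PLATE, plate)
            df.insert(1, WELL, well)
            df.insert(2, TREATMENT, "cpdX" if treated else DEFAULT_CONTROL)
            df.insert(3, MOA, "moa_X" if treated else None)
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    table = CellFeatureTable(
        data=data,
        features=("uniform", "shifted", "bimodal", "drift", "degenerate", "constant"),
    )
    expected = {
        "uniform_pooled_counts": [100, 100, 100, 100, 100],
        "uniform_drift_well": "w05",
        "uniform_drift_well_counts": drift_counts.tolist(),
        "uniform_regular_well_counts": regular_counts.tolist(),
        "uniform_drift_well_chi2": 736.0 / 20.0,  # sum((O-20)^2)/20
        "uniform_regular_well_chi2": 46.0 / 20.0,
        "chi2_df": 4,
    }
    return table, expected
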