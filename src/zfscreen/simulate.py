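"""Synthetic light-dark plates with known ground truth.

Generates 96-well behavioral plates shaped like the real assay: 5 semi-log
concentrations x 16 larvae plus 16 vehicle wells, 2-min bins over a
20-min dark acclimation / 40-min light / 40-min dark protocol.  Vehicle
larvae show the canonical profile — low, slowly drifting light-phase
activity, then a dark-transition startle burst that habituates toward a
plateau (dark > light on average).

Bin distances are Gamma distributed (right-skewed, non-negative) around a
deterministic phase mean, with a shared lognormal per-larva frailty that
induces within-larva correlation.  Chemical effects act multiplicatively on
interpretable drivers via Hill functions of concentration:

* ``light_level``        scales the whole light-phase mean;
* ``dark_level``         scales the whole dark-phase mean (plateau and
                         startle envelope together);
* ``startle_amplitude``  scales only the startle envelope;
* ``habituation_rate``   scales the within-dark decay rate.

Developmental-toxicity observations are drawn from per-status logistic
dose-response curves; larvae failing the behavior-inclusion rule produce no
locomotor profile.  Everything is reproducible: the seed is explicit in every
public operation and there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .devtox import MALFORMATION_TYPES, WellObservation, behavior_inclusion
from .endpoints import ENDPOINT_NAMES, LocomotorProfile, compute_endpoints
from .normalization import VehicleReference, apply_reference

__all__ = [
    "DevtoxCurve", "DevtoxModel", "HillEffect", "Protocol",
    "SimulationConfig", "GroundTruth", "noiseless_profile",
    "profiles_to_table", "simulate_larva", "simulate_plate", "true_bmc",
]

DRIVERS = ("light_level", "dark_level", "startle_amplitude", "habituation_rate")


class HillEffect(BaseModel):
    """Fractional suppression of a driver: E(c) = emax * c^h / (c^h + ac50^h)."""

    emax: float = Field(ge=0.0, le=1.0)
    ac50: float = Field(gt=0.0)
    hill: float = Field(default=1.5, gt=0.0)

    def at(self, conc: float) -> float:
        if conc <= 0 or self.emax == 0:
            return 0.0
        ch = conc**self.hill
        return self.emax * ch / (ch + self.ac50**self.hill)


class DevtoxCurve(BaseModel):
    """Logistic dose-response for one observed-status probability."""

    base: float = Field(default=0.0, ge=0.0, le=1.0)
    emax: float = Field(default=0.0, ge=0.0, le=1.0)
    ec50: float = Field(default=100.0, gt=0.0)
    hill: float = Field(default=2.0, gt=0.0)

    def at(self, conc: float) -> float:
        if conc <= 0:
            return self.base
        ch = conc**self.hill
        return self.base + (self.emax - self.base) * ch / (ch + self.ec50**self.hill)


class DevtoxModel(BaseModel):
    """Per-status curves; statuses are resolved in precedence order."""

    dead: DevtoxCurve = DevtoxCurve(base=0.01)
    not_hatched: DevtoxCurve = DevtoxCurve(base=0.01)
    severely_abnormal: DevtoxCurve = DevtoxCurve(base=0.0)
    abnormal: DevtoxCurve = DevtoxCurve(base=0.02)


class Protocol(BaseModel):
    """Assay timing (minutes) and photic metadata."""

    acclimation_min: float = 20.0
    light_min: float = 40.0
    dark_min: float = 40.0
    bin_width_min: float = 2.0
    acclimation_lux: float = 12.0
    light_lux: float = 3500.0
    dark_lux: float = 12.0

    @model_validator(mode="after")
    def _divisible(self) -> "Protocol":
        for v in (self.acclimation_min, self.light_min, self.dark_min):
            if abs(round(v / self.bin_width_min) - v / self.bin_width_min) > 1e-9:
                raise ValueError("phase durations must be divisible by bin width")
        return self


class SimulationConfig(BaseModel):
    """Study-condition parameters of the generator (units in field names)."""

    chemical: str = "chemX"
    protocol: Protocol = Protocol()
    concentrations_uM: list[float] = Field(
        default_factory=lambda: [100.0 * 10 ** (-0.5 * k) for k in range(5)]
    )
    n_per_group: int = 16
    n_vehicle: int = 16
    randomize_layout: bool = True

    acclimation_mean_cm: float = 4.0       # cm/bin during dark acclimation
    light_baseline_cm: float = 3.0         # cm/bin at light onset
    light_trend_cm_per_bin: float = -0.02  # slow drift across the light phase
    dark_plateau_cm: float = 5.0           # asymptotic dark activity
    startle_amplitude_cm: float = 7.0      # excess activity at dark onset
    habituation_decay_per_bin: float = 0.25
    frailty_sd_log: float = 0.3            # lognormal per-larva multiplier
    gamma_shape: float = 4.0               # bin noise: CV = 1/sqrt(shape)

    effects: dict[str, HillEffect] = Field(default_factory=dict)
    devtox: DevtoxModel = DevtoxModel()

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        unknown = set(self.effects) - set(DRIVERS)
        if unknown:
            raise ValueError(f"unknown effect driver(s): {sorted(unknown)}")
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("tested concentrations must be > 0")
        if self.n_per_group * len(self.concentrations_uM) + self.n_vehicle > 96:
            raise ValueError("layout overflow: > 96 wells")
        for name in ("acclimation_mean_cm", "light_baseline_cm", "dark_plateau_cm",
                     "startle_amplitude_cm", "habituation_decay_per_bin",
                     "frailty_sd_log", "gamma_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    @property
    def active(self) -> bool:
        return any(e.emax > 0 for e in self.effects.values())

    def _mult(self, driver: str, conc: float) -> float:
        eff = self.effects.get(driver)
        return 1.0 if eff is None else 1.0 - eff.at(conc)

    def bin_means(self, conc: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Noiseless (acclimation, light, dark) bin means at one concentration."""
        p = self.protocol
        n_a = int(round(p.acclimation_min / p.bin_width_min))
        n_l = int(round(p.light_min / p.bin_width_min))
        n_d = int(round(p.dark_min / p.bin_width_min))
        accl = np.full(n_a, self.acclimation_mean_cm)
        i = np.arange(n_l)
        light = (self.light_baseline_cm + self.light_trend_cm_per_bin * i)
        light = np.maximum(light * self._mult("light_level", conc), 0.0)
        j = np.arange(n_d)
        decay = self.habituation_decay_per_bin * self._mult("habituation_rate", conc)
        envelope = (self.startle_amplitude_cm
                    * self._mult("startle_amplitude", conc) * np.exp(-decay * j))
        dark = (self.dark_plateau_cm + envelope) * self._mult("dark_level", conc)
        return accl, light, np.maximum(dark, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    chemical: str
    active: bool
    effects: dict[str, HillEffect]

    def to_dict(self) -> dict:
        return {
            "chemical": self.chemical,
            "active": self.active,
            "effects": {k: v.model_dump() for k, v in self.effects.items()},
        }


def _assemble(config: SimulationConfig, accl, light, dark, *, larva_id, plate_id,
              conc) -> LocomotorProfile:
    p = config.protocol
    dist = np.concatenate([accl, light, dark])
    n = len(dist)
    starts = np.arange(n) * p.bin_width_min
    phases = np.array(
        ["acclimation"] * len(accl) + ["light"] * len(light) + ["dark"] * len(dark),
        dtype=object,
    )
    return LocomotorProfile(
        larva_id=larva_id, plate_id=plate_id, chemical=config.chemical,
        concentration=conc, bin_starts=starts, phases=phases, distances=dist,
        bin_width=p.bin_width_min,
    )


def noiseless_profile(config: SimulationConfig, conc: float) -> LocomotorProfile:
    """Deterministic forward evaluation (frailty = 1, no sampling noise)."""
    accl, light, dark = config.bin_means(conc)
    return _assemble(config, accl, light, dark,
                     larva_id="noiseless", plate_id="forward", conc=conc)


def simulate_larva(
    config: SimulationConfig, conc: float, rng: np.random.Generator,
    *, larva_id: str = "L0", plate_id: str = "P0",
) -> LocomotorProfile:
    """Draw one larva's binned profile at one concentration."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    accl, light, dark = config.bin_means(conc)
    mu = np.concatenate([accl, light, dark])
    frailty = float(np.exp(rng.normal(-config.frailty_sd_log**2 / 2.0,
                                      config.frailty_sd_log)))
    mu = np.maximum(mu * frailty, 1e-6)
    k = config.gamma_shape
    dist = rng.gamma(shape=k, scale=mu / k)
    n_a, n_l = len(accl), len(light)
    return _assemble(config, dist[:n_a], dist[n_a:n_a + n_l], dist[n_a + n_l:],
                     larva_id=larva_id, plate_id=plate_id, conc=conc)


def _draw_observation(
    config: SimulationConfig, well: str, conc: float, rng: np.random.Generator
) -> WellObservation:
    d = config.devtox
    if rng.random() < d.dead.at(conc):
        return WellObservation(well=well, alive=False, hatched=rng.random() < 0.5)
    if rng.random() < d.not_hatched.at(conc):
        return WellObservation(well=well, alive=True, hatched=False)
    malf_pool = sorted(MALFORMATION_TYPES)
    if rng.random() < d.severely_abnormal.at(conc):
        m = frozenset(rng.choice(malf_pool, size=2, replace=False))
        return WellObservation(well=well, alive=True, hatched=True,
                               malformations=m, severity="severe")
    if rng.random() < d.abnormal.at(conc):
        m = frozenset([str(rng.choice(malf_pool))])
        return WellObservation(well=well, alive=True, hatched=True,
                               malformations=m, severity="mild")
    return WellObservation(well=well, alive=True, hatched=True)


def simulate_plate(
    config: SimulationConfig, seed: int, plate_id: str = "plate1"
) -> tuple[list[LocomotorProfile], pd.DataFrame, list[WellObservation], GroundTruth]:
    """One 96-well plate: profiles, plate map, observations, ground truth.

    Treatments (n_per_group per tested concentration plus n_vehicle vehicle
    wells) are assigned to wells in a seeded random arrangement; wells
    failing :func:`zfscreen.devtox.behavior_inclusion` yield no profile.
    """
    rng = np.random.default_rng(seed)
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    treatments = [0.0] * config.n_vehicle
    for conc in config.concentrations_uM:
        treatments += [conc] * config.n_per_group
    treatments += [np.nan] * (96 - len(treatments))  # unused wells
    order = rng.permutation(96) if config.randomize_layout else np.arange(96)
    assignment = {wells[i]: treatments[j] for i, j in enumerate(order)}

    plate_rows, profiles, observations = [], [], []
    for well in wells:
        conc = assignment[well]
        if np.isnan(conc):
            continue
        chem = "DMSO" if conc == 0 else config.chemical
        obs = _draw_observation(config, well, conc, rng)
        observations.append(obs)
        included = behavior_inclusion(obs)
        plate_rows.append({
            "plate_id": plate_id, "well": well, "chemical": chem,
            "conc_uM": conc, "included": included,
        })
        if included:
            profiles.append(
                simulate_larva(config, conc, rng, larva_id=well, plate_id=plate_id)
            )
    plate_map = pd.DataFrame(plate_rows)
    truth = GroundTruth(chemical=config.chemical, active=config.active,
                        effects=dict(config.effects))
    return profiles, plate_map, observations, truth


def profiles_to_table(profiles: list[LocomotorProfile]) -> pd.DataFrame:
    """Long-format bin table in the schema the endpoints module consumes."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "plate_id": p.plate_id, "well": p.larva_id, "larva_id": p.larva_id,
            "chemical": p.chemical, "conc_uM": p.concentration,
            "bin_start_min": p.bin_starts, "phase": p.phases,
            "distance_cm": p.distances,
        }))
    return pd.concat(frames, ignore_index=True)


def observations_to_table(observations: list[WellObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        row = {"well": o.well, "alive": o.alive, "hatched": o.hatched,
               "severity": o.severity}
        for m in sorted(MALFORMATION_TYPES):
            row[m] = m in o.malformations
        rows.append(row)
    return pd.DataFrame(rows)


def true_bmc(
    config: SimulationConfig,
    endpoint: str,
    reference: VehicleReference,
    bmr: float = 1.349,
    tol: float = 1e-6,
) -> float | None:
    """Ground-truth BMC by noiseless forward evaluation.

    The endpoint's noiseless value as a function of concentration is pushed
    through the frozen vehicle transform; the true BMC is the smallest tested
    concentration where the standardized shift from the vehicle value reaches
    ``bmr``.  None when the endpoint is unaffected or never reaches the BMR.
    """
    if endpoint not in ENDPOINT_NAMES:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if not config.active:
        return None
    ref = reference[endpoint]

    def shift(conc: float) -> float:
        e = compute_endpoints(noiseless_profile(config, conc))[endpoint]
        e0 = compute_endpoints(noiseless_profile(config, 0.0))[endpoint]
        r, _ = apply_reference(np.array([e, e0]), ref)
        return abs(float(r[0] - r[1]))

    c_lo = min(config.concentrations_uM) / 100.0
    c_hi = max(config.concentrations_uM)
    grid = np.logspace(np.log10(c_lo), np.log10(c_hi), 200)
    vals = np.array([shift(c) for c in grid])
    if np.all(vals < bmr):
        return None
    i = int(np.argmax(vals >= bmr))
    if i == 0:
        return float(grid[0])
    lo, hi = grid[i - 1], grid[i]
    while abs(shift(hi) - bmr) > tol and (hi - lo) > 1e-12:
        mid = np.sqrt(lo * hi)
        if shift(mid) < bmr:
            lo = mid
        else:
            hi = mid
    return float(hi)
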