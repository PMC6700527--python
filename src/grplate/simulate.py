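"""Generative model for multi-center drug dose-response plate experiments.

Emulates the replicate structure of a single-cell-line (MCF 10A-like)
drug-response study: 384-well plates seeded at 750 cells/well, an untreated
plate assayed at the time of drug addition (t = 0), and technical-triplicate
treated plates assayed after 72 h, repeated over three biological replicates
(days).  Eight drugs are each dispensed in an 8-point sqrt(10)-fold dilution
series alongside >= 24 randomized vehicle-control wells per plate.

The growth model is exactly consistent with the GR statistic: a drug at
concentration ``c`` scales the control growth rate by the fraction
``g(c) = log2(1 + GR_true(c))`` so that a noise-free dataset round-trips
through GR computation to the true curve identically.

Noise hierarchy
---------------
* well level   - multiplicative log-normal measurement noise on counts
                 (parameterized by a CV), followed by integer quantization;
* plate level  - log-normal multiplier on the growth rate shared by all
                 wells of a plate (cancels in GR, as plate-matched controls
                 are the point of the design);
* day level    - log-normal multiplier on the growth rate shared by a
                 biological replicate, plus a log-normal day-to-day jitter
                 of each drug's potency (GEC50).  The potency jitter is the
                 channel that makes biological replicates genuinely noisier
                 than technical ones: growth-rate multipliers shared by
                 treated and control wells cancel in the GR statistic by
                 construction.

An additive spatial edge field depresses growth near plate borders, and a
drug-dependent per-cell surrogate bias emulates ATP-content (CellTiter-Glo
style) readouts diverging from direct cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .plate_io import (
    CONTROL,
    UNTREATED_T0,
    PLATE_DIMS_384,
    CapacityError,
    dose_series,
    randomize_layout,
)

__all__ = [
    "TrueDoseResponse",
    "BiphasicDoseResponse",
    "DrugSpec",
    "NoiseModel",
    "EdgeField",
    "DeadFractionModel",
    "SimulationConfig",
    "default_config",
    "load_config",
    "generate_dataset",
    "generate_timecourse",
    "generate_untreated_plate",
    "surrogate_signal",
]


# ---------------------------------------------------------------------------
# true response models


@dataclass(frozen=True)
class TrueDoseResponse:
    """Ground-truth sigmoidal GR dose-response with optional time dependence.

    GR_true(c) = 1 - (1 - gr_inf) * e(c) with Hill-type fractional effect
    e(c) = (c/gec50)^hill / (1 + (c/gec50)^hill).

    ``onset_tau``/``adaptation_tau`` (hours) modulate the fractional effect
    over time: e(c, t) = e(c) * (1 - exp(-t/onset_tau)) * exp(-t/adaptation_tau)
    (each factor is 1 when its tau is 0).  A growing onset emulates drugs
    that need time to act; a decay emulates adaptation (efficacy fading at
    late times, as seen for some EGFR-family inhibitors).
    """

    gr_inf: float
    gec50: float
    hill: float
    onset_tau: float = 0.0
    adaptation_tau: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.gr_inf <= 1.0:
            raise ValueError(f"gr_inf must be in [-1, 1], got {self.gr_inf}")
        if self.gec50 <= 0:
            raise ValueError(f"gec50 must be > 0, got {self.gec50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if self.onset_tau < 0 or self.adaptation_tau < 0:
            raise ValueError("time constants must be >= 0")

    def fractional_effect(self, conc) -> np.ndarray:
        """Dose-only fractional effect in [0, 1); 0 at c = 0, -> 1 at high dose."""
        conc = np.asarray(conc, dtype=float)
        ratio = np.power(conc / self.gec50, self.hill)
        return ratio / (1.0 + ratio)

    def time_factor(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        f = np.ones_like(t)
        if self.onset_tau > 0:
            f = f * (1.0 - np.exp(-t / self.onset_tau))
        if self.adaptation_tau > 0:
            f = f * np.exp(-t / self.adaptation_tau)
        return f

    def gr(self, conc, t=None, gec50=None) -> np.ndarray:
        """Instantaneous true GR at dose ``conc`` (and time ``t`` if given).

        ``gec50`` overrides the nominal potency (used for day-level jitter).
        """
        eff = (
            self.fractional_effect(conc)
            if gec50 is None
            else TrueDoseResponse(self.gr_inf, gec50, self.hill).fractional_effect(conc)
        )
        if t is not None:
            eff = eff * self.time_factor(t)
        return 1.0 - (1.0 - self.gr_inf) * eff

    def growth_fraction_integral(self, conc, duration_h: float, gec50=None,
                                 substep_h: float = 0.25) -> np.ndarray:
        """Integral over [0, T] of g(c, t) = log2(1 + GR_true(c, t)) in hours.

        Exact (g * T) when both time constants are zero; trapezoidal on a
        fine grid otherwise.
        """
        conc = np.atleast_1d(np.asarray(conc, dtype=float))
        if self.onset_tau == 0 and self.adaptation_tau == 0:
            g = np.log2(np.maximum(self.gr(conc, gec50=gec50) + 1.0, 1e-12))
            return g * duration_h
        n = max(int(math.ceil(duration_h / substep_h)), 2)
        t = np.linspace(0.0, duration_h, n + 1)
        gr_ct = self.gr(conc[:, None], t[None, :], gec50=gec50)
        g = np.log2(np.maximum(gr_ct + 1.0, 1e-12))
        return np.trapezoid(g, t, axis=1)

    def endpoint_gr(self, conc, duration_h: float) -> np.ndarray:
        """GR implied by an endpoint assay after ``duration_h`` of exposure.

        Equals gr(conc) exactly for time-invariant drugs; otherwise the
        time-averaged growth fraction, 2**(mean g) - 1.
        """
        integral = self.growth_fraction_integral(conc, duration_h)
        return np.power(2.0, integral / duration_h) - 1.0


@dataclass(frozen=True)
class BiphasicDoseResponse:
    """Two-phase decline: a plateau at ``gr_mid`` after the first transition,
    then a second decline to ``gr_inf`` at much higher doses.

    Models poly-selective inhibitors (dasatinib-like) whose secondary
    targets engage only above the conventional dose range, so that fits on
    a truncated series miss the second decline entirely.
    """

    gr_mid: float
    gr_inf: float
    gec50_1: float
    gec50_2: float
    hill_1: float = 2.0
    hill_2: float = 2.0

    def gr(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        e1 = (conc / self.gec50_1) ** self.hill_1
        e1 = e1 / (1.0 + e1)
        e2 = (conc / self.gec50_2) ** self.hill_2
        e2 = e2 / (1.0 + e2)
        return 1.0 - (1.0 - self.gr_mid) * e1 - (self.gr_mid - self.gr_inf) * e2


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DrugSpec:
    """One drug: its true response, optional per-drug top dose (uM) and the
    per-cell surrogate-signal multiplier reached at full drug effect.

    ``atp_bias`` > 1 emulates drugs (e.g. CDK4/6 inhibitors) that arrest
    cells which then enlarge, inflating ATP content per cell; < 1 emulates
    metabolic suppression without death.
    """

    name: str
    response: TrueDoseResponse
    atp_bias: float = 1.0
    top_dose: float | None = None

    def __post_init__(self):
        if self.atp_bias < 0:
            raise ValueError(f"atp_bias must be >= 0, got {self.atp_bias}")


@dataclass(frozen=True)
class NoiseModel:
    """Hierarchical noise (all parameters >= 0; zero disables a level).

    cv_well: coefficient of variation of multiplicative log-normal count
        noise per measurement (5% is typical of automated imaging counts).
    sigma_plate / sigma_day: natural-log scale of log-normal growth-rate
        multipliers shared per plate / per biological replicate (centered
        so the multiplier has mean 1).
    sigma_day_potency: natural-log scale of a per-(day, drug) log-normal
        GEC50 multiplier - the day-to-day biological variability channel.
    """

    cv_well: float = 0.05
    sigma_plate: float = 0.02
    sigma_day: float = 0.05
    sigma_day_potency: float = 0.10

    def __post_init__(self):
        for name in ("cv_well", "sigma_plate", "sigma_day", "sigma_day_potency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EdgeField:
    """Multiplicative spatial depression of growth near plate borders.

    Wells in edge band d (0 = outermost) are scaled by
    ``1 - edge_frac * max(0, 1 - d/depth)``; bands >= depth are unaffected.
    """

    edge_frac: float = 0.0
    depth: int = 2

    def multiplier(self, row, col, dims) -> np.ndarray:
        n_rows, n_cols = dims
        row = np.asarray(row)
        col = np.asarray(col)
        d = np.minimum.reduce([row - 1, col - 1, n_rows - row, n_cols - col])
        return 1.0 - self.edge_frac * np.maximum(0.0, 1.0 - d / self.depth)


@dataclass(frozen=True)
class DeadFractionModel:
    """Dead-cell fraction = baseline + slope * (1 - (GR_true + 1)/2), clipped.

    Ties death to drug effect so that dead-inclusive vs dead-exclusive
    counting discrepancies can be emulated downstream.
    """

    baseline: float = 0.02
    slope: float = 0.30

    def fraction(self, gr_true) -> np.ndarray:
        f = self.baseline + self.slope * (1.0 - (np.asarray(gr_true) + 1.0) / 2.0)
        return np.clip(f, 0.0, 0.95)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative model for one simulated study."""

    drugs: tuple[DrugSpec, ...]
    doses_per_drug: int = 8
    top_dose: float = 10.0
    dilution_fold: float = math.sqrt(10.0)
    n_bio: int = 3
    n_plates: int = 3
    n_wells: int = 3
    n_controls: int = 24
    n_t0_wells: int = 384
    plate_dims: tuple[int, int] = PLATE_DIMS_384
    seeding: float = 750.0
    k_ctrl: float = 0.05  # doublings/h -> 20 h doubling time
    duration_h: float = 72.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    edge: EdgeField = field(default_factory=EdgeField)
    dead: DeadFractionModel = field(default_factory=DeadFractionModel)
    center_id: str = "center_1"
    scientist_id: str = "scientist_B"
    seed: int | None = 0

    def __post_init__(self):
        if not self.drugs:
            raise ValueError("at least one drug required")
        if self.doses_per_drug < 1 or self.n_bio < 1 or self.n_plates < 1 \
                or self.n_wells < 1 or self.n_controls < 1 or self.n_t0_wells < 1:
            raise ValueError("all counts must be >= 1")
        if self.seeding < 1:
            raise ValueError("seeding must be >= 1 cell/well")
        if self.k_ctrl <= 0:
            raise ValueError("k_ctrl must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")

    def doses_for(self, drug: DrugSpec) -> np.ndarray:
        top = drug.top_dose if drug.top_dose is not None else self.top_dose
        return dose_series(top, self.doses_per_drug, self.dilution_fold)

    def wells_per_plate(self) -> int:
        return len(self.drugs) * self.doses_per_drug * self.n_wells + self.n_controls

    def drug_map(self) -> dict[str, DrugSpec]:
        return {d.name: d for d in self.drugs}


def default_config(seed: int | None = 0, **overrides) -> SimulationConfig:
    """The study-like default: 8 drugs x 8 doses, 3 days x 3 plates x 3 wells.

    Drug parameters are plausible for an MCF 10A-like non-transformed line:
    a potent cytostatic MEK inhibitor, a partially cytotoxic multi-kinase
    inhibitor, a time-adapting EGFR-family inhibitor, a time-invariant
    topoisomerase poison, a cytostatic CDK4/6 inhibitor with strong ATP
    bias, and others.  Per-drug top doses follow the standard design
    (1-10 uM stocks, sqrt(10)-fold series).
    """
    drugs = (
        DrugSpec("trametinib", TrueDoseResponse(0.10, 0.005, 2.0), 1.2, top_dose=1.0),
        DrugSpec("dasatinib", TrueDoseResponse(-0.40, 0.10, 1.5), 1.1, top_dose=10.0),
        DrugSpec("neratinib",
                 TrueDoseResponse(-0.60, 0.05, 2.0, onset_tau=4.0, adaptation_tau=60.0),
                 1.05, top_dose=3.16),
        DrugSpec("etoposide", TrueDoseResponse(-0.20, 1.0, 1.2), 1.9, top_dose=10.0),
        DrugSpec("palbociclib", TrueDoseResponse(0.25, 0.30, 1.8), 2.0, top_dose=3.16),
        DrugSpec("alpelisib", TrueDoseResponse(0.30, 1.0, 1.5), 1.5, top_dose=10.0),
        DrugSpec("paclitaxel", TrueDoseResponse(-0.30, 0.003, 2.5), 1.2, top_dose=1.0),
        DrugSpec("vorinostat", TrueDoseResponse(0.05, 1.5, 1.3), 1.3, top_dose=10.0),
    )
    return SimulationConfig(drugs=drugs, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# YAML config


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["drugs"] = [
        {"name": s.name, "atp_bias": s.atp_bias, "top_dose": s.top_dose,
         **asdict(s.response)}
        for s in config.drugs
    ]
    d["plate_dims"] = list(config.plate_dims)
    return d


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML document (see save_config)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    drugs = tuple(
        DrugSpec(
            name=spec["name"],
            response=TrueDoseResponse(
                gr_inf=spec["gr_inf"],
                gec50=spec["gec50"],
                hill=spec["hill"],
                onset_tau=spec.get("onset_tau", 0.0),
                adaptation_tau=spec.get("adaptation_tau", 0.0),
            ),
            atp_bias=spec.get("atp_bias", 1.0),
            top_dose=spec.get("top_dose"),
        )
        for spec in d.pop("drugs")
    )
    noise = NoiseModel(**d.pop("noise", {}))
    edge = EdgeField(**d.pop("edge", {}))
    dead = DeadFractionModel(**d.pop("dead", {}))
    if "plate_dims" in d:
        d["plate_dims"] = tuple(d["plate_dims"])
    return SimulationConfig(drugs=drugs, noise=noise, edge=edge, dead=dead, **d)


# ---------------------------------------------------------------------------
# generation internals


def _day_effects(config: SimulationConfig, rng: np.random.Generator):
    """Per-bio-rep growth multiplier and per-(bio-rep, drug) GEC50 multiplier.

    Log-normal with log-mean -sigma^2/2 so the multiplier has expectation 1.
    """
    nz = config.noise
    day_growth = np.exp(
        rng.normal(-nz.sigma_day**2 / 2, nz.sigma_day, size=config.n_bio)
        if nz.sigma_day > 0 else np.zeros(config.n_bio)
    )
    day_potency = np.exp(
        rng.normal(0.0, nz.sigma_day_potency, size=(config.n_bio, len(config.drugs)))
        if nz.sigma_day_potency > 0 else np.zeros((config.n_bio, len(config.drugs)))
    )
    return day_growth, day_potency


def _noisy_counts(expected: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1, then integer quantization.

    Quantization is part of the noise model: with cv = 0 the exact expected
    counts are returned so that noise-free datasets round-trip through GR
    computation identically.
    """
    expected = np.asarray(expected, dtype=float)
    if cv <= 0:
        return np.maximum(expected, 0.0)
    s = math.sqrt(math.log1p(cv * cv))
    noisy = expected * np.exp(rng.normal(-s * s / 2, s, size=expected.shape))
    return np.maximum(np.rint(noisy), 0.0)


def _emit_well(records: list, config: SimulationConfig, *, bio_rep, plate_id,
               row, col, drug, conc, timepoint_h, viable, gr_true,
               rng: np.random.Generator, timecourse: bool = False):
    """Append viable/nuclei/dead rows for one well (endpoint datasets) or a
    single viable row (time courses, where only live nuclei are imaged)."""
    viable = _noisy_counts(viable, config.noise.cv_well, rng)
    base = {
        "center_id": config.center_id,
        "scientist_id": config.scientist_id,
        "bio_rep": bio_rep,
        "plate_id": plate_id,
        "row": row,
        "col": col,
        "drug": drug,
        "concentration": conc,
        "timepoint_h": timepoint_h,
    }
    records.append({**base, "readout_type": "viable_count", "value": float(viable)})
    if timecourse:
        return
    f = float(config.dead.fraction(gr_true))
    nuclei = viable / (1.0 - f)
    if config.noise.cv_well > 0:
        nuclei = np.rint(nuclei)
    records.append({**base, "readout_type": "nuclei_count", "value": float(nuclei)})
    records.append({**base, "readout_type": "dead_count",
                    "value": float(nuclei - viable)})


def _treated_plate_layouts(config: SimulationConfig, rng: np.random.Generator):
    """One randomized layout per treated plate position (shared across days
    would be unrealistic; a fresh randomization is drawn per plate)."""
    treatments = []
    for drug in config.drugs:
        for conc in config.doses_for(drug):
            treatments.extend([(drug.name, float(conc))] * config.n_wells)
    treatments.extend([(CONTROL, 0.0)] * config.n_controls)
    if len(treatments) > config.plate_dims[0] * config.plate_dims[1]:
        raise CapacityError(
            f"{len(treatments)} wells needed exceed plate capacity "
            f"{config.plate_dims[0] * config.plate_dims[1]}"
        )
    return randomize_layout(treatments, config.plate_dims, rng)


# ---------------------------------------------------------------------------
# public generators


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Endpoint dataset: untreated t=0 plate(s) + treated plates per bio rep.

    Expected treated count is seeding * 2**(k * T * g) with
    g = log2(1 + GR_true) (time-averaged when the drug is time-varying),
    k the day/plate-modulated control growth rate, all scaled by the edge
    field and well noise.  Returns a tidy well table with viable, nuclei
    and dead readouts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    day_growth, day_potency = _day_effects(config, rng)
    nz = config.noise
    n_rows, n_cols = config.plate_dims
    if config.n_t0_wells > n_rows * n_cols:
        raise CapacityError(
            f"n_t0_wells={config.n_t0_wells} exceeds plate capacity {n_rows * n_cols}"
        )
    records: list[dict] = []
    T = config.duration_h
    for b in range(config.n_bio):
        bio_rep = b + 1
        # untreated plate assayed at the moment of drug addition (t = 0)
        t0_plate = f"b{bio_rep}_t0"
        t0_wells = [
            (r, c)
            for r in range(1, n_rows + 1)
            for c in range(1, n_cols + 1)
        ][: config.n_t0_wells]
        for r, c in t0_wells:
            _emit_well(records, config, bio_rep=bio_rep, plate_id=t0_plate,
                       row=r, col=c, drug=UNTREATED_T0, conc=0.0, timepoint_h=0.0,
                       viable=config.seeding, gr_true=1.0, rng=rng)
        for p in range(config.n_plates):
            plate_id = f"b{bio_rep}_p{p + 1}"
            plate_growth = (
                math.exp(rng.normal(-nz.sigma_plate**2 / 2, nz.sigma_plate))
                if nz.sigma_plate > 0 else 1.0
            )
            k_eff = config.k_ctrl * day_growth[b] * plate_growth
            layout = _treated_plate_layouts(config, rng)
            drug_idx = {d.name: i for i, d in enumerate(config.drugs)}
            dmap = config.drug_map()
            for (r, c), (drug_name, conc, role) in sorted(layout.assignment.items()):
                edge_mult = float(config.edge.multiplier(r, c, config.plate_dims))
                if role == "control":
                    expected = config.seeding * 2.0 ** (k_eff * T) * edge_mult
                    gr_true = 1.0
                else:
                    spec = dmap[drug_name]
                    gec50_day = spec.response.gec50 * day_potency[b, drug_idx[drug_name]]
                    integral = spec.response.growth_fraction_integral(
                        conc, T, gec50=gec50_day
                    ).item()
                    expected = config.seeding * 2.0 ** (k_eff * integral) * edge_mult
                    gr_true = float(2.0 ** (integral / T) - 1.0)
                _emit_well(records, config, bio_rep=bio_rep, plate_id=plate_id,
                           row=r, col=c, drug=drug_name, conc=conc,
                           timepoint_h=T, viable=expected, gr_true=gr_true, rng=rng)
    return pd.DataFrame.from_records(records)


def generate_timecourse(
    config: SimulationConfig,
    interval_h: float = 2.0,
    duration_h: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Live-cell time course: per-well viable counts at t = 0, dt, 2 dt, ...

    Drug efficacy evolves with the drugs' onset/adaptation time constants so
    instantaneous GR can rise or fall over the assay.  Per-observation
    measurement noise only; each well's underlying trajectory is smooth.
    """
    if interval_h <= 0:
        raise ValueError(f"interval_h must be > 0, got {interval_h}")
    duration_h = float(config.duration_h if duration_h is None else duration_h)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    day_growth, day_potency = _day_effects(config, rng)
    nz = config.noise
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    records: list[dict] = []
    drug_idx = {d.name: i for i, d in enumerate(config.drugs)}
    dmap = config.drug_map()
    for b in range(config.n_bio):
        bio_rep = b + 1
        for p in range(config.n_plates):
            plate_id = f"b{bio_rep}_p{p + 1}"
            plate_growth = (
                math.exp(rng.normal(-nz.sigma_plate**2 / 2, nz.sigma_plate))
                if nz.sigma_plate > 0 else 1.0
            )
            k_eff = config.k_ctrl * day_growth[b] * plate_growth
            layout = _treated_plate_layouts(config, rng)
            for (r, c), (drug_name, conc, role) in sorted(layout.assignment.items()):
                edge_mult = float(config.edge.multiplier(r, c, config.plate_dims))
                if role == "control":
                    log2_traj = np.log2(config.seeding) + k_eff * times
                else:
                    spec = dmap[drug_name]
                    gec50_day = spec.response.gec50 * day_potency[b, drug_idx[drug_name]]
                    integrals = np.array([
                        spec.response.growth_fraction_integral(
                            conc, t, gec50=gec50_day).item() if t > 0 else 0.0
                        for t in times
                    ])
                    log2_traj = np.log2(config.seeding) + k_eff * integrals
                counts = 2.0 ** log2_traj
                if config.edge.edge_frac > 0:
                    # edge depression develops with time, fully expressed at endpoint
                    counts = counts * (
                        1.0 + (edge_mult - 1.0) * times / max(times[-1], 1e-9)
                    )
                for t, x in zip(times, counts):
                    _emit_well(records, config, bio_rep=bio_rep, plate_id=plate_id,
                               row=r, col=c, drug=drug_name, conc=conc,
                               timepoint_h=float(t), viable=x, gr_true=1.0,
                               rng=rng, timecourse=True)
    return pd.DataFrame.from_records(records)


def generate_untreated_plate(
    config: SimulationConfig,
    duration_h: float = 96.0,
    seed: int | None = None,
) -> np.ndarray:
    """Full plate of untreated growth (edge-effect QC fixture): a (rows, cols)
    matrix of viable counts after ``duration_h`` of unperturbed growth under
    the config's edge field and well noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_rows, n_cols = config.plate_dims
    rows, cols = np.meshgrid(
        np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij"
    )
    edge_mult = config.edge.multiplier(rows, cols, config.plate_dims)
    expected = config.seeding * 2.0 ** (config.k_ctrl * duration_h) * edge_mult
    return _noisy_counts(expected, config.noise.cv_well, rng)


def surrogate_signal(well_table: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Surrogate-assay (ATP-content style) readout derived from viable counts.

    signal = viable_count * per_cell_signal, with per_cell_signal
    interpolating from 1 (no effect) to the drug's atp_bias at full
    fractional effect.  Controls and untreated wells carry unit per-cell
    signal, so the surrogate equals the count there exactly.
    """
    viable = well_table[well_table["readout_type"] == "viable_count"].copy()
    dmap = config.drug_map()
    treated = ~viable["drug"].isin((CONTROL, UNTREATED_T0))
    unknown = sorted(set(viable.loc[treated, "drug"]) - set(dmap))
    if unknown:
        raise KeyError(f"drug(s) without surrogate-bias annotation: {unknown}")
    per_cell = np.ones(len(viable))
    for name, spec in dmap.items():
        mask = (viable["drug"] == name).to_numpy()
        if not mask.any():
            continue
        eff = spec.response.fractional_effect(
            viable.loc[mask, "concentration"].to_numpy()
        )
        per_cell[mask] = 1.0 + (spec.atp_bias - 1.0) * eff
    out = viable.copy()
    out["readout_type"] = "surrogate_signal"
    out["value"] = viable["value"].to_numpy() * per_cell
    return out
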