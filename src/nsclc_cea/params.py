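"""Domain types and parameter-file I/O for the NSCLC cost-effectiveness model.

The model compares seven first-line treatment strategies for advanced
non-small cell lung cancer (six immunotherapy regimens plus platinum-doublet
chemotherapy) within PD-L1 expression strata.  All inputs — per-6-week drug
and administration costs, health-state utilities, second-line therapy mixes,
hazard ratios with 95% CIs per stratum, and the reference-arm PFS/OS curves —
live in a :class:`ParameterSet`, loaded from a YAML file whose schema is
documented in ``docs/parameter_file.md``.

Every scalar a sensitivity analysis may vary is addressable by a dotted path
(``drug_costs.pemetrexed``, ``strategy.pembro_chemo.utility_pf``,
``hr.nivo_ipi.lt1.os`` …) via :func:`get_parameter` / :func:`set_parameter`.
"""

from __future__ import annotations

import copy
import enum
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterValidationError, SchemaError, UnknownParameterError

logger = logging.getLogger(__name__)

REFERENCE_STRATEGY = "chemotherapy"

#: therapy classes a progressing patient may receive second line
SECONDLINE_CLASSES = ("chemo", "immunotherapy", "targeted")

#: drugs whose per-6-week costs the fixture declares
KNOWN_DRUGS = (
    "pembrolizumab", "nivolumab", "ipilimumab", "atezolizumab", "bevacizumab",
    "pemetrexed", "carboplatin", "paclitaxel", "docetaxel", "erlotinib",
)

CHEMO_BACKBONES = ("none", "histology_weighted", "paclitaxel_carboplatin")


class Stratum(str, enum.Enum):
    """PD-L1 tumour expression stratum."""

    ALL = "all"
    LT1 = "lt1"          # PD-L1 < 1%
    PD1_49 = "1to49"     # PD-L1 1-49%
    GE50 = "ge50"        # PD-L1 >= 50%

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STRATA = tuple(s.value for s in Stratum)


def as_stratum(label) -> Stratum:
    try:
        return Stratum(label)
    except ValueError:
        raise SchemaError(f"unknown PD-L1 stratum {label!r}; expected one of {STRATA}") from None


ENDPOINTS = ("PFS", "OS")


@dataclass
class SurvivalCurve:
    """A digitised (or synthetic) Kaplan-Meier curve: surviving proportion vs weeks."""

    endpoint: str
    times: np.ndarray     # weeks, strictly increasing, starting at 0
    survival: np.ndarray  # proportions in [0, 1], non-increasing, survival[0] == 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Step-function (last value carried forward) evaluation, KM-style."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.survival[idx]

    def violations(self, name: str = "curve") -> list[str]:
        out = []
        if self.endpoint not in ENDPOINTS:
            out.append(f"{name}.endpoint: {self.endpoint!r} not in {ENDPOINTS}")
        if len(self.times) < 2:
            out.append(f"{name}: fewer than 2 points")
            return out
        if self.times[0] != 0:
            out.append(f"{name}: times must start at 0 (got {self.times[0]})")
        if np.any(np.diff(self.times) <= 0):
            out.append(f"{name}: times not strictly increasing")
        if self.survival[0] != 1.0:
            out.append(f"{name}: survival[0] must be 1 (got {self.survival[0]})")
        if np.any((self.survival < 0) | (self.survival > 1)):
            out.append(f"{name}: survival values outside [0, 1]")
        rising = np.nonzero(np.diff(self.survival) > 0)[0]
        if rising.size:
            out.append(f"{name}: survival rises at time index {int(rising[0]) + 1}")
        return out


@dataclass
class HazardRatioSpec:
    """Hazard ratio of an immunotherapy arm vs chemotherapy with its 95% CI."""

    point: float
    low: float
    high: float

    def violations(self, name: str) -> list[str]:
        out = []
        if not (self.low > 0 and self.point > 0 and self.high > 0):
            out.append(f"{name}: hazard ratio and CI bounds must be > 0")
        elif not (self.low <= self.point <= self.high):
            out.append(f"{name}: CI must bracket the point ({self.low} <= {self.point} <= {self.high})")
        return out


@dataclass
class DistributionSpec:
    """PSA sampling distribution for one parameter path."""

    family: str  # beta | gamma | dirichlet | lognormal_from_ci | fixed
    params: tuple = ()

    FAMILIES = ("beta", "gamma", "dirichlet", "lognormal_from_ci", "fixed")

    def violations(self, name: str) -> list[str]:
        out = []
        if self.family not in self.FAMILIES:
            out.append(f"{name}: unknown distribution family {self.family!r}")
            return out
        p = tuple(self.params)
        if self.family in ("beta", "gamma") and (len(p) != 2 or any(x <= 0 for x in p)):
            out.append(f"{name}: {self.family} needs 2 positive parameters, got {p}")
        if self.family == "dirichlet" and (len(p) < 2 or any(x <= 0 for x in p)):
            out.append(f"{name}: dirichlet needs >= 2 positive parameters, got {p}")
        if self.family == "lognormal_from_ci" and (len(p) != 3 or any(x <= 0 for x in p)):
            out.append(f"{name}: lognormal_from_ci needs (point, ci_low, ci_high) > 0, got {p}")
        return out


@dataclass
class StrategyDefinition:
    """One first-line regimen: cost structure, utility, HRs and second-line mix.

    Per-cycle cost fields (``io_cost_per_cycle``, ``chemo_cost_per_cycle``,
    ``pem_maintenance_cost_per_cycle``, ``beva_cost_per_cycle``) are derived
    from the drug-cost table by :meth:`ParameterSet.refresh_costs`.
    """

    name: str
    io_drugs: list = field(default_factory=list)
    io_max_cycles: int = 17            # 2-year immunotherapy cap at 6-week cycles
    induction_chemo_cycles: int = 0    # 6-week cycles with platinum-doublet cost
    chemo_backbone: str = "none"
    pemetrexed_maintenance: bool = False
    bevacizumab_maintenance: bool = False
    utility_pf: float = 0.79
    secondline_mix: dict = field(default_factory=dict)   # class -> proportion
    ae_lump_cost: float = 0.0          # one-time adverse-event cost at entry
    hr_by_stratum: dict = field(default_factory=dict)    # stratum -> {"PFS": spec, "OS": spec}
    # derived:
    io_cost_per_cycle: float = 0.0
    chemo_cost_per_cycle: float = 0.0
    pem_maintenance_cost_per_cycle: float = 0.0
    beva_cost_per_cycle: float = 0.0

    @property
    def is_reference(self) -> bool:
        return self.name == REFERENCE_STRATEGY

    def available_strata(self) -> tuple:
        """Strata the strategy can be evaluated in (HR presence; reference everywhere)."""
        if self.is_reference:
            return STRATA
        return tuple(s for s in STRATA if s in self.hr_by_stratum)

    def violations(self) -> list[str]:
        name = f"strategy.{self.name}"
        out = []
        if self.io_max_cycles < 0:
            out.append(f"{name}.io_max_cycles: must be >= 0")
        if self.induction_chemo_cycles < 0:
            out.append(f"{name}.induction_chemo_cycles: must be >= 0")
        if self.chemo_backbone not in CHEMO_BACKBONES:
            out.append(f"{name}.chemo_backbone: {self.chemo_backbone!r} not in {CHEMO_BACKBONES}")
        if not (0.0 <= self.utility_pf <= 1.0):
            out.append(f"{name}.utility_pf: {self.utility_pf} outside [0, 1]")
        if self.ae_lump_cost < 0:
            out.append(f"{name}.ae_lump_cost: must be >= 0")
        total = 0.0
        for cls, p in self.secondline_mix.items():
            if cls not in SECONDLINE_CLASSES:
                out.append(f"{name}.secondline_mix.{cls}: unknown therapy class")
            if not (0.0 <= p <= 1.0):
                out.append(f"{name}.secondline_mix.{cls}: {p} outside [0, 1]")
            total += p
        if total > 1.0 + 1e-9:
            out.append(f"{name}.secondline_mix: proportions sum to {total:.3f} > 1")
        for d in self.io_drugs:
            if d not in KNOWN_DRUGS:
                out.append(f"{name}.io_drugs: unknown drug {d!r}")
        for stratum, by_ep in self.hr_by_stratum.items():
            if stratum not in STRATA:
                out.append(f"{name}.hr.{stratum}: unknown stratum")
                continue
            for ep in ENDPOINTS:
                if ep not in by_ep:
                    out.append(f"hr.{self.name}.{stratum}: missing {ep} hazard ratio")
                else:
                    out.extend(by_ep[ep].violations(f"hr.{self.name}.{stratum}.{ep.lower()}"))
        return out


@dataclass
class EconomicParams:
    """Global economic settings (cycle structure, discounting, shared costs/utilities)."""

    cycle_length_weeks: float = 6.0
    annual_discount: float = 0.03
    wtp: float = 150_000.0
    admin_cost_per_cycle: float = 678.0
    bsc_cost_per_cycle: float = 4574.0
    utility_pd: float = 0.72
    squamous_fraction: float = 0.28
    secondline_unit_costs: dict = field(default_factory=dict)  # class -> USD per 6 weeks
    secondline_duration_cycles: int = 4
    horizon_max_years: float = 30.0
    stop_alive_fraction: float = 1e-4
    bsc_in_pf: bool = False  # accrue best-supportive-care cost in PF as well as PD

    def horizon_cycles(self) -> int:
        return int(self.horizon_max_years * 52.0 / self.cycle_length_weeks)

    def violations(self) -> list[str]:
        out = []
        if self.cycle_length_weeks <= 0:
            out.append("econ.cycle_length_weeks: must be > 0")
        if self.annual_discount < 0:
            out.append("econ.annual_discount: must be >= 0")
        if not (0.0 <= self.utility_pd <= 1.0):
            out.append(f"econ.utility_pd: {self.utility_pd} outside [0, 1]")
        if not (0.0 <= self.squamous_fraction <= 1.0):
            out.append(f"econ.squamous_fraction: {self.squamous_fraction} outside [0, 1]")
        for key in ("admin_cost_per_cycle", "bsc_cost_per_cycle", "wtp"):
            if getattr(self, key) < 0:
                out.append(f"econ.{key}: must be >= 0")
        for cls in SECONDLINE_CLASSES:
            if cls not in self.secondline_unit_costs:
                out.append(f"econ.secondline_unit_costs.{cls}: missing")
            elif self.secondline_unit_costs[cls] < 0:
                out.append(f"econ.secondline_unit_costs.{cls}: must be >= 0")
        if self.secondline_duration_cycles < 0:
            out.append("econ.secondline_duration_cycles: must be >= 0")
        if self.horizon_max_years <= 0:
            out.append("econ.horizon_max_years: must be > 0")
        if not (0.0 <= self.stop_alive_fraction < 1.0):
            out.append("econ.stop_alive_fraction: must be in [0, 1)")
        return out


@dataclass
class ParameterSet:
    """Everything the pipeline needs: strategies, economics, curves, PSA/DSA specs."""

    strategies: dict = field(default_factory=dict)       # name -> StrategyDefinition
    econ: EconomicParams = field(default_factory=EconomicParams)
    drug_costs: dict = field(default_factory=dict)       # drug -> USD per 6 weeks
    curves: dict = field(default_factory=dict)           # stratum -> {"PFS": curve, "OS": curve}
    distributions: dict = field(default_factory=dict)    # path -> DistributionSpec
    dsa_ranges: dict = field(default_factory=dict)       # path -> (low, high)

    def refresh_costs(self) -> None:
        """Recompute derived per-cycle strategy costs from the drug-cost table.

        The chemotherapy backbone is the histology-weighted mean
        ``sq*(paclitaxel+carboplatin) + (1-sq)*(pemetrexed+carboplatin)``;
        pemetrexed maintenance applies only to the non-squamous fraction.
        """
        sq = self.econ.squamous_fraction
        dc = self.drug_costs
        for sd in self.strategies.values():
            sd.io_cost_per_cycle = float(sum(dc.get(d, 0.0) for d in sd.io_drugs))
            if sd.chemo_backbone == "histology_weighted":
                sd.chemo_cost_per_cycle = (
                    sq * (dc.get("paclitaxel", 0.0) + dc.get("carboplatin", 0.0))
                    + (1.0 - sq) * (dc.get("pemetrexed", 0.0) + dc.get("carboplatin", 0.0))
                )
            elif sd.chemo_backbone == "paclitaxel_carboplatin":
                sd.chemo_cost_per_cycle = dc.get("paclitaxel", 0.0) + dc.get("carboplatin", 0.0)
            else:
                sd.chemo_cost_per_cycle = 0.0
            sd.pem_maintenance_cost_per_cycle = (
                (1.0 - sq) * dc.get("pemetrexed", 0.0) if sd.pemetrexed_maintenance else 0.0
            )
            sd.beva_cost_per_cycle = (
                dc.get("bevacizumab", 0.0) if sd.bevacizumab_maintenance else 0.0
            )

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def strategies_in(self, stratum) -> list:
        s = as_stratum(stratum).value
        return [sd for sd in self.strategies.values() if s in sd.available_strata()]


# ---------------------------------------------------------------------------
# validation

def validate_parameter_set(ps: ParameterSet) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid).

    Reports, never raises: every violation names the offending dotted path.
    """
    out: list[str] = []
    if REFERENCE_STRATEGY not in ps.strategies:
        out.append(f"strategies: reference strategy {REFERENCE_STRATEGY!r} is missing")
    for name, sd in ps.strategies.items():
        if sd.name != name:
            out.append(f"strategy.{name}: name field disagrees ({sd.name!r})")
        out.extend(sd.violations())
    out.extend(ps.econ.violations())
    for drug, cost in ps.drug_costs.items():
        if cost < 0:
            out.append(f"drug_costs.{drug}: must be >= 0")
    for path, spec in ps.distributions.items():
        out.extend(spec.violations(f"distributions.{path}"))
    for path, rng in ps.dsa_ranges.items():
        lo, hi = rng
        if lo > hi:
            out.append(f"dsa_ranges.{path}: low {lo} > high {hi}")
    if ps.curves:
        for stratum, by_ep in ps.curves.items():
            if stratum not in STRATA:
                out.append(f"curves.{stratum}: unknown stratum")
                continue
            for ep in ENDPOINTS:
                if ep not in by_ep:
                    out.append(f"curves.{stratum}: missing {ep} curve")
                else:
                    out.extend(by_ep[ep].violations(f"curves.{stratum}.{ep}"))
        for sd in ps.strategies.values():
            for stratum in sd.available_strata():
                if stratum not in ps.curves:
                    out.append(
                        f"curves.{stratum}: required by strategy.{sd.name} but absent"
                    )
    return sorted(set(out))


# ---------------------------------------------------------------------------
# survival-curve file I/O (WebPlotDigitizer-style two-column exports)

def read_survival_curve(path, endpoint: str) -> SurvivalCurve:
    """Read a two-column delimited curve file (``time_weeks,survival``).

    Comma- or tab-separated, optional header, '.' decimal.  Repairs applied,
    each with a logged warning: a (0, 1.0) anchor is prepended if absent,
    values are clamped into [0, 1], and digitisation jitter (locally rising
    survival) is flattened by a running minimum.
    """
    if endpoint not in ENDPOINTS:
        raise SchemaError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.replace("\t", ",").split(",")
            cells = [c.strip() for c in cells if c.strip() != ""]
            if len(cells) < 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                t, s = float(cells[0]), float(cells[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise SchemaError(f"{path}:{lineno}: non-numeric cell") from None
            rows.append((t, s))
    if len(rows) < 2:
        raise SchemaError(f"{path}: fewer than 2 data rows")
    rows.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in rows])
    surv = np.array([r[1] for r in rows])
    if np.any((surv < 0) | (surv > 1)):
        logger.warning("%s: survival values clamped into [0, 1]", path)
        surv = np.clip(surv, 0.0, 1.0)
    if times[0] != 0.0:
        logger.warning("%s: prepending (0, 1.0) anchor", path)
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    elif surv[0] != 1.0:
        logger.warning("%s: survival at t=0 reset to 1.0", path)
        surv[0] = 1.0
    mono = np.minimum.accumulate(surv)
    if np.any(mono != surv):
        logger.warning("%s: non-monotone survival repaired by running minimum", path)
    return SurvivalCurve(endpoint=endpoint, times=times, survival=mono)


def write_survival_curve(curve: SurvivalCurve, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_weeks,survival\n")
        for t, s in zip(curve.times, curve.survival):
            fh.write(f"{float(t)!r},{float(s)!r}\n")


# ---------------------------------------------------------------------------
# parameter-file I/O

def _hr_from_raw(raw, where: str) -> HazardRatioSpec:
    try:
        point, low, high = (float(x) for x in raw)
    except (TypeError, ValueError):
        raise SchemaError(f"{where}: expected [point, ci_low, ci_high]") from None
    return HazardRatioSpec(point=point, low=low, high=high)


def _parameter_set_from_dict(doc: dict, base_dir: Path | None) -> ParameterSet:
    if not isinstance(doc, dict):
        raise SchemaError("top level of parameter file must be a mapping")
    ps = ParameterSet()

    econ_raw = doc.get("econ", {})
    if not isinstance(econ_raw, dict):
        raise SchemaError("econ: must be a mapping")
    econ = EconomicParams()
    for key, value in econ_raw.items():
        if not hasattr(econ, key):
            raise SchemaError(f"econ.{key}: unknown key")
        setattr(econ, key, value)
    ps.econ = econ

    ps.drug_costs = {str(k): float(v) for k, v in doc.get("drug_costs", {}).items()}

    strategies_raw = doc.get("strategies")
    if not strategies_raw:
        raise SchemaError("strategies: section is missing or empty")
    hr_raw = doc.get("hazard_ratios", {})
    for name, body in strategies_raw.items():
        sd = StrategyDefinition(name=str(name))
        for key, value in (body or {}).items():
            if key in ("io_cost_per_cycle", "chemo_cost_per_cycle") or not hasattr(sd, key):
                raise SchemaError(f"strategy.{name}.{key}: unknown key")
            setattr(sd, key, value)
        for stratum, by_ep in (hr_raw.get(name) or {}).items():
            stratum = as_stratum(stratum).value
            sd.hr_by_stratum[stratum] = {
                ep.upper(): _hr_from_raw(raw, f"hazard_ratios.{name}.{stratum}.{ep}")
                for ep, raw in by_ep.items()
            }
        ps.strategies[sd.name] = sd
    for name in hr_raw:
        if name not in ps.strategies:
            raise SchemaError(f"hazard_ratios.{name}: no such strategy")

    for stratum, by_ep in (doc.get("curves") or {}).items():
        stratum = as_stratum(stratum).value
        ps.curves[stratum] = {}
        for ep, ref in by_ep.items():
            ep = ep.upper()
            if isinstance(ref, str):
                if base_dir is None:
                    raise SchemaError(f"curves.{stratum}.{ep}: file reference without a base dir")
                ps.curves[stratum][ep] = read_survival_curve(base_dir / ref, ep)
            else:  # inline {times: [...], survival: [...]}
                ps.curves[stratum][ep] = SurvivalCurve(
                    endpoint=ep,
                    times=np.asarray(ref["times"], dtype=float),
                    survival=np.asarray(ref["survival"], dtype=float),
                )

    for path, spec in (doc.get("distributions") or {}).items():
        if not isinstance(spec, dict) or "family" not in spec:
            raise SchemaError(f"distributions.{path}: expected mapping with a 'family' key")
        ps.distributions[str(path)] = DistributionSpec(
            family=str(spec["family"]), params=tuple(spec.get("params", ()))
        )

    for path, rng in (doc.get("dsa_ranges") or {}).items():
        try:
            lo, hi = (float(x) for x in rng)
        except (TypeError, ValueError):
            raise SchemaError(f"dsa_ranges.{path}: expected [low, high]") from None
        ps.dsa_ranges[str(path)] = (lo, hi)

    ps.refresh_costs()
    return ps


def load_parameter_set(config_path) -> ParameterSet:
    """Load and validate a YAML parameter file; curve paths resolve relative to it."""
    config_path = Path(config_path)
    try:
        with open(config_path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{config_path}: not valid YAML ({exc})") from None
    ps = _parameter_set_from_dict(doc, config_path.parent)
    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterValidationError(violations)
    return ps


def write_parameter_set(ps: ParameterSet, config_path, curve_dir: str = "curves") -> Path:
    """Write a parameter set (and any curves) back to disk; inverse of load."""
    config_path = Path(config_path)
    config_path.parent.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    econ = {k: v for k, v in vars(ps.econ).items()}
    doc["econ"] = econ
    doc["drug_costs"] = dict(ps.drug_costs)
    doc["strategies"] = {}
    doc["hazard_ratios"] = {}
    derived = (
        "name", "hr_by_stratum", "io_cost_per_cycle", "chemo_cost_per_cycle",
        "pem_maintenance_cost_per_cycle", "beva_cost_per_cycle",
    )
    for name, sd in ps.strategies.items():
        doc["strategies"][name] = {
            k: v for k, v in vars(sd).items() if k not in derived
        }
        if sd.hr_by_stratum:
            doc["hazard_ratios"][name] = {
                stratum: {
                    ep.lower(): [spec.point, spec.low, spec.high]
                    for ep, spec in by_ep.items()
                }
                for stratum, by_ep in sd.hr_by_stratum.items()
            }
    if not doc["hazard_ratios"]:
        del doc["hazard_ratios"]
    if ps.curves:
        doc["curves"] = {}
        for stratum, by_ep in ps.curves.items():
            doc["curves"][stratum] = {}
            for ep, curve in by_ep.items():
                rel = f"{curve_dir}/{stratum}_{ep.lower()}.csv"
                write_survival_curve(curve, config_path.parent / rel)
                doc["curves"][stratum][ep.lower()] = rel
    if ps.distributions:
        doc["distributions"] = {
            path: {"family": spec.family, "params": list(spec.params)}
            for path, spec in ps.distributions.items()
        }
    if ps.dsa_ranges:
        doc["dsa_ranges"] = {path: list(rng) for path, rng in ps.dsa_ranges.items()}
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


def builtin_parameter_file() -> Path:
    """Path of the shipped parameter table (costs, utilities, HRs; no curves)."""
    return Path(resources.files("nsclc_cea.data") / "strategy_parameters.yaml")


def builtin_parameter_set() -> ParameterSet:
    """The shipped parameter table as a ParameterSet (curves must be added separately)."""
    return load_parameter_set(builtin_parameter_file())


def published_basecase_file() -> Path:
    """Path of the shipped published base-case results table (frontier validation input)."""
    return Path(resources.files("nsclc_cea.data") / "published_basecase.csv")


# ---------------------------------------------------------------------------
# dotted-path parameter addressing (DSA / PSA plumbing)

def _resolve(ps: ParameterSet, path: str):
    """Return (container, key) for a dotted path, so it can be read or written."""
    parts = path.split(".")
    try:
        head = parts[0]
        if head == "econ":
            if len(parts) == 3 and parts[1] == "secondline_unit_costs":
                return ps.econ.secondline_unit_costs, parts[2]
            if len(parts) == 2 and hasattr(ps.econ, parts[1]):
                return vars(ps.econ), parts[1]
        elif head == "drug_costs" and len(parts) == 2 and parts[1] in ps.drug_costs:
            return ps.drug_costs, parts[1]
        elif head == "strategy":
            sd = ps.strategies[parts[1]]
            if len(parts) == 4 and parts[2] == "secondline_mix":
                if parts[3] in sd.secondline_mix:
                    return sd.secondline_mix, parts[3]
            elif len(parts) == 3 and hasattr(sd, parts[2]):
                return vars(sd), parts[2]
        elif head == "hr":
            sd = ps.strategies[parts[1]]
            spec = sd.hr_by_stratum[as_stratum(parts[2]).value][parts[3].upper()]
            attr = parts[4] if len(parts) == 5 else "point"
            if hasattr(spec, attr):
                return vars(spec), attr
    except (KeyError, IndexError, SchemaError):
        pass
    raise UnknownParameterError(f"no parameter at path {path!r}")


def get_parameter(ps: ParameterSet, path: str) -> float:
    container, key = _resolve(ps, path)
    return container[key]


def set_parameter(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with the addressed scalar replaced (derived costs refreshed)."""
    ps = ps.copy()
    container, key = _resolve(ps, path)
    container[key] = value
    ps.refresh_costs()
    return ps


def apply_overrides(ps: ParameterSet, overrides: dict) -> ParameterSet:
    """Apply many path -> value overrides with a single copy (PSA hot path)."""
    ps = ps.copy()
    for path, value in overrides.items():
        container, key = _resolve(ps, path)
        container[key] = value
    ps.refresh_costs()
    return ps
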