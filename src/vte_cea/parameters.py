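"""Model parameters: loading, validation and the shipped defaults.

All probabilities and unit costs of the decision model live in one
human-editable YAML document (:data:`DEFAULT_CONFIG`).  A user config needs
to state only the keys it overrides; everything else falls back to the
shipped defaults, which are the published point estimates (30-day event
probabilities and 2013 US$ unit costs).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "StrategyParams",
    "SharedParams",
    "CostTable",
    "FunnelCounts",
    "PopulationConstants",
    "ParameterBundle",
    "Violation",
    "ConfigurationError",
    "ConfigFormatError",
    "DEFAULT_CONFIG",
    "load_parameters",
    "validate_parameters",
    "bundle_checksum",
    "dump_parameters",
]

STRATEGIES = ("LMWH", "UFH", "NONE")


class ConfigurationError(ValueError):
    """A required parameter key is missing or has an inadmissible value."""


class ConfigFormatError(ValueError):
    """The configuration file could not be parsed."""


@dataclass(frozen=True)
class StrategyParams:
    """Strategy-specific inputs: prophylaxis efficacy, safety and drug cost."""

    strategy_id: str
    p_dvt: float
    p_bleed: float
    p_hit: float
    prophylaxis_cost: float


@dataclass(frozen=True)
class SharedParams:
    """Probabilities shared by all strategies.

    Covers adverse-event consequences, DVT/PE treatment efficacy and safety,
    natural history, and the diagnostic test characteristics.  The CT and V/Q
    scan rows are carried individually; the default tree wires in only their
    arithmetic mean (``pe_scan_avg_*``), which is cross-checked at load time.
    """

    p_major_given_bleed: float
    p_death_given_major_bleed: float
    p_symptomatic_given_hit: float
    p_death_given_symptomatic_hit: float
    p_bleed_given_dvt_tx: float
    p_hit_given_dvt_tx: float
    p_pe_given_dvt_tx: float
    p_death_given_pe_tx_pos: float
    p_death_given_pe_tx_neg: float
    p_sudden_death_given_pe: float
    p_pe_given_untreated_dvt: float
    p_death_given_untreated_pe: float
    p_death_underlying: float
    dvt_clin_sens: float
    dvt_clin_spec: float
    dvt_us_sens: float
    dvt_us_spec: float
    pe_clin_sens: float
    pe_clin_spec: float
    pe_scan_avg_sens: float
    pe_scan_avg_spec: float
    pe_ct_sens: float | None = None
    pe_ct_spec: float | None = None
    pe_vq_sens: float | None = None
    pe_vq_spec: float | None = None


@dataclass(frozen=True)
class CostTable:
    """Unit costs (2013 US$) of diagnosis, treatment and adverse events."""

    major_bleed: float
    minor_bleed: float
    asymptomatic_hit: float
    symptomatic_hit: float
    treated_dvt: float
    treated_pe: float
    dvt_diagnosis: float
    pe_diagnosis: float


@dataclass(frozen=True)
class FunnelCounts:
    """Eligibility-funnel tallies from the US survey arm.

    ``age_los_eligible`` is an optional intermediate count used by the
    synthetic-admissions filter (records passing the age >= 40 and length of
    stay >= 2 days screen); the published funnel does not report it
    separately because enrolment already applied those criteria.
    """

    enrolled: int
    medical_ward: int
    at_vte_risk: int
    receiving_prophylaxis: int
    contraindicated: int
    age_los_eligible: int | None = None


@dataclass(frozen=True)
class PopulationConstants:
    """Cohort size and the national-extrapolation constants."""

    cohort_size: int = 10_000
    endorse_counts: FunnelCounts = field(
        default_factory=lambda: FunnelCounts(9257, 5196, 2720, 1292, 331)
    )
    nis_eligible_total: int = 14_300_000
    at_risk_fraction: float = 0.511
    at_risk_iqr: tuple[float, float] = (0.448, 0.622)


@dataclass(frozen=True)
class ParameterBundle:
    """The full, validated parameter set of the model."""

    strategies: Mapping[str, StrategyParams]
    shared: SharedParams
    costs: CostTable
    population: PopulationConstants


@dataclass(frozen=True)
class Violation:
    """One invariant violation: the offending parameter, its value, and why."""

    parameter: str
    value: object
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.parameter}={self.value!r}: {self.message}"


def _read_default_config() -> dict:
    text = (resources.files("vte_cea") / "data" / "params_paper.yaml").read_text()
    return yaml.safe_load(text)


DEFAULT_CONFIG: dict = _read_default_config()

_SHARED_SECTIONS = (
    "consequences_of_aes",
    "dvt_treatment",
    "pe_treatment",
    "natural_history",
    "dvt_diagnosis",
    "pe_diagnosis",
)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _build_bundle(config: dict) -> ParameterBundle:
    try:
        strategies = {}
        for sid in STRATEGIES:
            raw = config["strategies"][sid]
            strategies[sid] = StrategyParams(strategy_id=sid, **raw)
        shared_kwargs: dict = {}
        for section in _SHARED_SECTIONS:
            shared_kwargs.update(config[section])
        shared = SharedParams(**shared_kwargs)
        costs = CostTable(**config["costs"])
        pop_raw = config["population"]
        population = PopulationConstants(
            cohort_size=int(config["cohort_size"]),
            endorse_counts=FunnelCounts(**pop_raw["endorse_counts"]),
            nis_eligible_total=int(pop_raw["nis_eligible_total"]),
            at_risk_fraction=float(pop_raw["at_risk_fraction"]),
            at_risk_iqr=tuple(pop_raw["at_risk_iqr"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration key: {exc.args[0]!r}") from exc
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    return ParameterBundle(strategies=strategies, shared=shared, costs=costs, population=population)


def load_parameters(config_path: str | Path | None = None) -> ParameterBundle:
    """Load and validate the parameter bundle.

    Parameters
    ----------
    config_path
        Optional YAML file.  Keys present override the shipped defaults;
        absent keys fall back to them.  ``None`` loads the defaults as-is.

    Raises
    ------
    ConfigFormatError
        If the file cannot be parsed as YAML or is not a mapping.
    ConfigurationError
        If a required key is missing or the resulting bundle violates a
        model invariant.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)
    if config_path is not None:
        path = Path(config_path)
        try:
            user = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigFormatError(f"cannot parse {path}: {exc}") from exc
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigFormatError(f"{path} must contain a mapping at top level")
        config = _deep_merge(config, user)
    bundle = _build_bundle(config)
    violations = validate_parameters(bundle)
    if violations:
        detail = "; ".join(str(v) for v in violations)
        raise ConfigurationError(f"invalid parameters: {detail}")
    return bundle


def _check_prob(name: str, value: float, out: list[Violation]) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(name, value, "probability must lie in [0, 1]"))


def validate_parameters(bundle: ParameterBundle) -> list[Violation]:
    """Return every invariant violation of the bundle (empty when valid)."""
    out: list[Violation] = []
    for sid, sp in bundle.strategies.items():
        for name in ("p_dvt", "p_bleed", "p_hit"):
            _check_prob(f"{sid}.{name}", getattr(sp, name), out)
        if sp.p_bleed + sp.p_hit > 1.0:
            out.append(
                Violation(
                    f"{sid}.p_bleed+p_hit",
                    sp.p_bleed + sp.p_hit,
                    "adverse events are mutually exclusive: p_bleed + p_hit must not exceed 1",
                )
            )
        if sp.prophylaxis_cost < 0:
            out.append(Violation(f"{sid}.prophylaxis_cost", sp.prophylaxis_cost, "cost must be >= 0"))
    if "NONE" in bundle.strategies and bundle.strategies["NONE"].p_hit != 0.0:
        out.append(
            Violation(
                "NONE.p_hit",
                bundle.strategies["NONE"].p_hit,
                "heparin-induced thrombocytopenia requires heparin exposure: must be 0 without prophylaxis",
            )
        )

    shared = bundle.shared
    for f in fields(SharedParams):
        value = getattr(shared, f.name)
        if value is not None:
            _check_prob(f"shared.{f.name}", value, out)
    # the averaged scan row must equal the mean of the CT and V/Q rows
    for avg_name, a, b in (
        ("pe_scan_avg_sens", shared.pe_ct_sens, shared.pe_vq_sens),
        ("pe_scan_avg_spec", shared.pe_ct_spec, shared.pe_vq_spec),
    ):
        if a is not None and b is not None:
            expected = (a + b) / 2.0
            got = getattr(shared, avg_name)
            if abs(got - expected) > 1e-9:
                out.append(
                    Violation(
                        f"shared.{avg_name}",
                        got,
                        f"must equal the mean of the CT and V/Q values ({expected:.6f})",
                    )
                )

    for f in fields(CostTable):
        value = getattr(bundle.costs, f.name)
        if value < 0:
            out.append(Violation(f"costs.{f.name}", value, "cost must be >= 0"))

    pop = bundle.population
    if pop.cohort_size < 1:
        out.append(Violation("cohort_size", pop.cohort_size, "cohort size must be >= 1"))
    ec = pop.endorse_counts
    chain = [
        ("enrolled", ec.enrolled),
        ("medical_ward", ec.medical_ward),
        ("at_vte_risk", ec.at_vte_risk),
        ("receiving_prophylaxis", ec.receiving_prophylaxis),
    ]
    for (up_name, up), (dn_name, dn) in zip(chain, chain[1:]):
        if dn > up:
            out.append(
                Violation(
                    f"endorse_counts.{dn_name}",
                    dn,
                    f"funnel counts must be non-increasing ({dn_name} > {up_name}={up})",
                )
            )
    for name, count in chain + [("contraindicated", ec.contraindicated)]:
        if count < 0:
            out.append(Violation(f"endorse_counts.{name}", count, "count must be >= 0"))
    if ec.contraindicated > ec.at_vte_risk:
        out.append(
            Violation(
                "endorse_counts.contraindicated",
                ec.contraindicated,
                "cannot exceed the at-risk count",
            )
        )
    _check_prob("population.at_risk_fraction", pop.at_risk_fraction, out)
    lo, hi = pop.at_risk_iqr
    _check_prob("population.at_risk_iqr[0]", lo, out)
    _check_prob("population.at_risk_iqr[1]", hi, out)
    if lo > hi:
        out.append(Violation("population.at_risk_iqr", pop.at_risk_iqr, "IQR low must be <= high"))
    if pop.nis_eligible_total < 0:
        out.append(Violation("population.nis_eligible_total", pop.nis_eligible_total, "must be >= 0"))
    return out


def dump_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    """Write the bundle back to a YAML config that reloads identically."""
    config: dict = {
        "cohort_size": bundle.population.cohort_size,
        "strategies": {
            sid: {
                k: v
                for k, v in asdict(sp).items()
                if k != "strategy_id"
            }
            for sid, sp in bundle.strategies.items()
        },
        "costs": asdict(bundle.costs),
        "population": {
            "endorse_counts": {
                k: v
                for k, v in asdict(bundle.population.endorse_counts).items()
                if v is not None
            },
            "nis_eligible_total": bundle.population.nis_eligible_total,
            "at_risk_fraction": bundle.population.at_risk_fraction,
            "at_risk_iqr": list(bundle.population.at_risk_iqr),
        },
    }
    shared = asdict(bundle.shared)
    for section in _SHARED_SECTIONS:
        config[section] = {
            k: shared[k] for k in DEFAULT_CONFIG[section] if shared.get(k) is not None
        }
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def bundle_checksum(bundle: ParameterBundle) -> str:
    """SHA-256 over a canonical JSON rendering; changes iff a parameter does."""
    payload = {
        "strategies": {sid: asdict(sp) for sid, sp in sorted(bundle.strategies.items())},
        "shared": asdict(bundle.shared),
        "costs": asdict(bundle.costs),
        "population": asdict(bundle.population),
    }
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(text.encode()).hexdigest()
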