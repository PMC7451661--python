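"""Study configuration files and result serialisation.

A study config is a small YAML document with up to four blocks::

    design:                 # DesignSpec fields; phi is required
      phi: 0.3
      variant: aboin_prior
    prior:                  # exactly one of pi0/mtd_guess or table
      pi0: [0.2, 0.45, 0.7, 0.45, 0.2]
      mtd_guess: 3
    scenarios:              # a packaged fixture name or inline scenarios
      fixture: table2-dlt30
    simulation:
      replicates: 10000
      seed: 1

Omitted design fields take the recommended defaults (phi1 = 0.6 phi,
phi2 = 1.4 phi, Delta = 0.4 phi, g1 = 0.4, g2 = 0.9, lead-in 6, cohorts of
3, at most 30 patients).  Result tables are written as TSV (diff-friendly,
full float precision) or JSON records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundaries import DesignSpec
from .priors import PriorTable, elicit_prior_table
from .simulate import DoseScenario, builtin_scenarios

__all__ = ["StudyConfig", "load_config", "write_results", "read_results"]

_DESIGN_KEYS = {
    "phi", "variant", "phi1", "phi2", "delta1", "delta2", "g1", "g2",
    "lead_in", "cohort_size", "max_n", "elimination_cutoff", "elimination_min_n",
}


@dataclass
class StudyConfig:
    """A fully validated study: design, optional prior, scenarios, simulation knobs."""

    design: DesignSpec
    prior: PriorTable | None
    scenarios: list[DoseScenario]
    replicates: int = 1000
    seed: int = 0
    f_over: float = 0.6
    f_under: float = 0.6


def _error(path: str, msg: str) -> ValueError:
    return ValueError(f"config field {path!r}: {msg}")


def _parse_design(block: dict) -> DesignSpec:
    if "phi" not in block:
        raise _error("design.phi", "required")
    unknown = set(block) - _DESIGN_KEYS
    if unknown:
        raise _error("design", f"unknown fields {sorted(unknown)}")
    return DesignSpec(**block)


def _parse_prior(block: dict | None, J_hint: int | None) -> PriorTable | None:
    if not block:
        return None
    has_table = "table" in block
    has_pi0 = "pi0" in block
    if has_table and has_pi0:
        raise _error("prior", "give either an explicit 'table' or a 'pi0' vector, not both")
    if has_table:
        return PriorTable(np.asarray(block["table"], dtype=float))
    if not has_pi0:
        raise _error("prior", "needs 'pi0' (+ 'mtd_guess') or 'table'")
    if "mtd_guess" not in block:
        raise _error("prior.mtd_guess", "required alongside 'pi0'")
    return elicit_prior_table(
        block["pi0"],
        int(block["mtd_guess"]),
        odds_low=float(block.get("odds_low", 10.0)),
        odds_high=float(block.get("odds_high", 0.1)),
    )


_FIXTURE_TARGETS = {"table2-dlt20": 0.2, "table2-dlt30": 0.3, "dlt20": 0.2, "dlt30": 0.3}


def _parse_scenarios(block, phi: float) -> list[DoseScenario]:
    if block is None:
        raise _error("scenarios", "required (fixture name or inline list)")
    if isinstance(block, dict) and "fixture" in block:
        name = block["fixture"]
        if name not in _FIXTURE_TARGETS:
            raise _error("scenarios.fixture", f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_TARGETS)}")
        return builtin_scenarios(_FIXTURE_TARGETS[name])
    if not isinstance(block, list):
        raise _error("scenarios", "expected a fixture mapping or a list of scenarios")
    out = []
    for i, item in enumerate(block):
        if "probs" not in item or "true_mtd" not in item:
            raise _error(f"scenarios[{i}]", "needs 'probs' and 'true_mtd'")
        out.append(
            DoseScenario(
                tuple(item["probs"]),
                int(item["true_mtd"]),
                label=str(item.get("label", f"scenario-{i + 1}")),
            )
        )
    return out


def load_config(path) -> StudyConfig:
    """Parse and validate a YAML study config; all defaults filled."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "design" not in raw:
        raise ValueError(f"{path}: expected a mapping with at least a 'design' block")
    design = _parse_design(dict(raw["design"]))
    scenarios = _parse_scenarios(raw.get("scenarios"), design.phi)
    prior = _parse_prior(raw.get("prior"), scenarios[0].J if scenarios else None)
    if design.uses_prior and prior is None:
        raise _error("prior", f"variant {design.variant!r} requires a prior block")
    J = {s.J for s in scenarios}
    if len(J) > 1:
        raise _error("scenarios", f"inconsistent numbers of doses {sorted(J)}")
    if prior is not None and scenarios and prior.J != scenarios[0].J:
        raise _error("prior", f"prior has {prior.J} doses but scenarios have {scenarios[0].J}")
    sim = dict(raw.get("simulation") or {})
    return StudyConfig(
        design=design,
        prior=prior,
        scenarios=scenarios,
        replicates=int(sim.get("replicates", 1000)),
        seed=int(sim.get("seed", 0)),
        f_over=float(sim.get("f_over", 0.6)),
        f_under=float(sim.get("f_under", 0.6)),
    )


def write_results(table: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a metrics table losslessly as TSV or JSON records."""
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        table.to_json(path, orient="records", indent=2, double_precision=15)
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")


def read_results(path, format: str = "tsv") -> pd.DataFrame:
    """Round-trip counterpart of :func:`write_results`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
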