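"""Simulation scenarios and the shipped scenario tables.

A :class:`Scenario` bundles a rate set with a target tip count, replicate
count, seed and label. Two fixture tables ship with the package: the
single-process asymmetry grid (``load_table1``) and the matched-bias grid
used for the reduced-model power comparison (``load_s4``, rates derived at
load time from stationary-frequency targets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .rates import RateSet
from .stationary import solve_rate_ratio


@dataclass(frozen=True)
class Scenario:
    rates: RateSet
    n_tips: int
    n_reps: int
    label: str = ""
    seed: int = 0
    #: process carrying the asymmetry, if any ("" for null scenarios)
    process: str = ""
    #: explicit symmetric rates for the matching null scenario, if known
    null_rates: RateSet | None = None

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError(f"n_tips must be >= 3, got {self.n_tips}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    def with_(self, **kw) -> "Scenario":
        return replace(self, **kw)

    def null_counterpart(self) -> "Scenario":
        """The matching symmetric-rates scenario.

        Uses ``null_rates`` when supplied; otherwise each process is made
        symmetric at the scenario's base (non-elevated) rate: lambda0 for
        speciation asymmetries, mu1 for extinction, q10 for character
        change.
        """
        if self.null_rates is not None:
            sym = self.null_rates
        else:
            r = self.rates
            la = r.lambda1 if self.process == "speciation" and r.lambda0 > r.lambda1 else r.lambda0
            mu = r.mu1 if self.process == "extinction" else r.mu0
            q = r.q10 if self.process == "character_change" else r.q01
            sym = RateSet(la, la, mu, mu, q, q)
        return self.with_(rates=sym, label=f"{self.label} (null)", process="")


def _data_path(name: str):
    return resources.files("bissekit").joinpath("data", name)


def load_scenario_file(path) -> list[Scenario]:
    """Read a YAML scenario file (explicit rates per entry)."""
    doc = yaml.safe_load(Path(path).read_text())
    return _parse(doc)


def load_table1() -> list[Scenario]:
    """The shipped single-process asymmetry grid (explicit rates)."""
    doc = yaml.safe_load(_data_path("table1.yaml").read_text())
    return _parse(doc)


def table1_metadata() -> list[dict]:
    """Raw rows of the shipped asymmetry grid, including the published
    mean percent of state-0 tips used in calibration checks."""
    doc = yaml.safe_load(_data_path("table1.yaml").read_text())
    return list(doc["scenarios"])


def load_s4() -> list[Scenario]:
    """The shipped matched-bias grid; rates solved from target_x_hat."""
    doc = yaml.safe_load(_data_path("s4.yaml").read_text())
    d = doc["defaults"]
    base = RateSet(d["base_lambda"], d["base_lambda"], d["base_mu"],
                   d["base_mu"], d["base_q"], d["base_q"])
    out = []
    for row in doc["scenarios"]:
        _, rates = solve_rate_ratio(row["process"], base, row["target_x_hat"])
        out.append(Scenario(rates=rates, n_tips=d["n_tips"], n_reps=d["n_reps"],
                            label=row["label"], process=row["process"],
                            null_rates=base))
    return out


def _parse(doc: dict) -> list[Scenario]:
    d = doc.get("defaults", {})
    out = []
    for row in doc["scenarios"]:
        rates = RateSet(row["lambda0"], row["lambda1"], row["mu0"],
                        row["mu1"], row["q01"], row["q10"])
        out.append(Scenario(
            rates=rates,
            n_tips=int(row.get("n_tips", d.get("n_tips", 500))),
            n_reps=int(row.get("n_reps", d.get("n_reps", 500))),
            label=str(row.get("label", "")),
            seed=int(row.get("seed", d.get("seed", 0))),
            process=str(row.get("process", "")),
        ))
    return out
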