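"""Rule-based drug-likeness / PAINS / ADMET gate for screening candidates.

The gate consumes a table of precomputed endpoint predictions per compound
(drug-likeness probability, PAINS alert count, F20% poor-bioavailability
probability, plasma protein binding percentage, acute oral toxicity and
skin sensitization probabilities) and applies fixed decision rules:

- drug-likeness: pass iff probability of being drug-like >= 0.5
- PAINS: pass iff zero alert substructures
- F20%: probability of oral bioavailability < 20%; pass iff <= 0.7
  (a probability *higher than* 0.7 flags a poor endpoint, so exactly 0.7
  still passes)
- PPB: plasma protein binding; pass iff strictly < 90%
- AOT and skin sensitization: pass iff probability <= 0.7

A compound passes overall iff every rule passes.  The predictive models
behind the endpoints are not part of this package — values arrive as a
CSV — but PAINS alert counting from structures is implemented locally
against RDKit's public PAINS filter catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from rdkit.Chem import FilterCatalog

from .compounds import CompoundSet

RULE_NAMES = ("druglikeness", "pains", "f20", "ppb", "aot", "skin_sens")

ADMET_COLUMNS = ["id", "druglikeness", "pains", "f20", "ppb", "aot", "skin_sens"]


@dataclass(frozen=True)
class ADMETRecord:
    """Predicted endpoint values for one compound."""

    compound_id: str
    druglikeness_prob: float
    pains_alerts: int
    f20_prob: float
    ppb_fraction: float  # percent, 0-100
    aot_prob: float
    skin_sens_prob: float

    def __post_init__(self):
        for name in ("druglikeness_prob", "f20_prob", "aot_prob", "skin_sens_prob"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0,1] for {self.compound_id!r}: {v}")
        if not np.isnan(self.ppb_fraction) and not 0 <= self.ppb_fraction <= 100:
            raise ValueError(
                f"ppb_fraction out of [0,100] for {self.compound_id!r}: "
                f"{self.ppb_fraction}"
            )
        if self.pains_alerts < 0:
            raise ValueError(f"pains_alerts negative for {self.compound_id!r}")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the gate rules (defaults as documented above)."""

    druglikeness_min: float = 0.5   # pass iff prob >= (non-strict)
    pains_max: int = 0              # pass iff alerts <=
    f20_max: float = 0.7            # pass iff prob <= (non-strict)
    ppb_max: float = 90.0           # pass iff percent < (strict)
    aot_max: float = 0.7            # pass iff prob <=
    skin_sens_max: float = 0.7      # pass iff prob <=


@dataclass(frozen=True)
class GateVerdict:
    compound_id: str
    verdicts: dict[str, bool]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.verdicts.values())

    @property
    def failed_rules(self) -> list[str]:
        return [r for r in RULE_NAMES if not self.verdicts[r]]


_pains_catalog = None


def _get_pains_catalog():
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _pains_catalog = FilterCatalog.FilterCatalog(params)
    return _pains_catalog


def count_pains_alerts(cs: CompoundSet) -> pd.Series:
    """Number of PAINS alert substructure matches per compound.

    Uses the public PAINS catalog bundled with RDKit (families A/B/C).
    """
    catalog = _get_pains_catalog()
    counts = {r.id: len(catalog.GetMatches(r.mol())) for r in cs}
    return pd.Series(counts, name="pains").loc[cs.ids]


def apply_gate(rec: ADMETRecord, rules: RuleConfig = RuleConfig()) -> GateVerdict:
    """Evaluate every rule for one record; missing (NaN) fields fail."""
    checks: dict[str, tuple[float, bool]] = {
        "druglikeness": (rec.druglikeness_prob,
                         rec.druglikeness_prob >= rules.druglikeness_min),
        "pains": (rec.pains_alerts, rec.pains_alerts <= rules.pains_max),
        "f20": (rec.f20_prob, rec.f20_prob <= rules.f20_max),
        "ppb": (rec.ppb_fraction, rec.ppb_fraction < rules.ppb_max),
        "aot": (rec.aot_prob, rec.aot_prob <= rules.aot_max),
        "skin_sens": (rec.skin_sens_prob, rec.skin_sens_prob <= rules.skin_sens_max),
    }
    verdicts: dict[str, bool] = {}
    reasons: dict[str, str] = {}
    for rule, (value, ok) in checks.items():
        if isinstance(value, float) and np.isnan(value):
            verdicts[rule] = False
            reasons[rule] = "missing"
        else:
            verdicts[rule] = bool(ok)
    return GateVerdict(rec.compound_id, verdicts, reasons)


def records_from_table(df: pd.DataFrame) -> list[ADMETRecord]:
    """Build ADMETRecords from a CSV-shaped table.

    Expected header: ``id,druglikeness,pains,f20,ppb,aot,skin_sens`` with
    PPB as a percent (a trailing ``%`` in the cell is accepted).
    """
    missing = [c for c in ADMET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ADMET table missing columns: {missing}")
    recs = []
    for _, row in df.iterrows():
        ppb = row["ppb"]
        if isinstance(ppb, str):
            ppb = float(ppb.rstrip("%"))
        recs.append(
            ADMETRecord(
                compound_id=str(row["id"]),
                druglikeness_prob=float(row["druglikeness"]),
                pains_alerts=int(row["pains"]),
                f20_prob=float(row["f20"]),
                ppb_fraction=float(ppb),
                aot_prob=float(row["aot"]),
                skin_sens_prob=float(row["skin_sens"]),
            )
        )
    return recs


def gate_table(
    records: list[ADMETRecord] | pd.DataFrame,
    rules: RuleConfig = RuleConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Apply the gate to a batch; return per-compound verdicts + summary.

    Summary holds per-rule failure counts and the ordered overall-pass list.
    Duplicate compound ids are a hard error.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_table(records)
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids in ADMET table: {dupes}")
    verdicts = [apply_gate(r, rules) for r in records]
    table = pd.DataFrame(
        {
            "id": ids,
            **{rule: [v.verdicts[rule] for v in verdicts] for rule in RULE_NAMES},
            "overall": [v.overall for v in verdicts],
            "failed_rules": [";".join(v.failed_rules) for v in verdicts],
        }
    )
    summary = {
        "n": len(records),
        "n_pass": int(table["overall"].sum()),
        "pass_ids": table.loc[table["overall"], "id"].tolist(),
        "rule_failures": {
            rule: int((~table[rule]).sum()) for rule in RULE_NAMES
        },
    }
    return table, summary


class AdmetGate(BaseEstimator):
    """sklearn-style wrapper: predict() returns the overall pass flag.

    Stateless rule classifier — fit() only validates parameters so the gate
    composes with pipelines and grid search over thresholds.
    """

    def __init__(self, druglikeness_min: float = 0.5, pains_max: int = 0,
                 f20_max: float = 0.7, ppb_max: float = 90.0,
                 aot_max: float = 0.7, skin_sens_max: float = 0.7):
        self.druglikeness_min = druglikeness_min
        self.pains_max = pains_max
        self.f20_max = f20_max
        self.ppb_max = ppb_max
        self.aot_max = aot_max
        self.skin_sens_max = skin_sens_max

    def _rules(self) -> RuleConfig:
        return RuleConfig(**{k: v for k, v in self.get_params().items()})

    def fit(self, X=None, y=None):
        self.rules_ = self._rules()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        table, _ = gate_table(X, self._rules())
        return table["overall"].to_numpy()
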