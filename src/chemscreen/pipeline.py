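"""Configuration-driven orchestration of the full screening protocol.

``run_screen`` executes the funnel — load/standardize compounds, descriptor
PCA space with boundary box and curve distance, fingerprint similarity
prioritization, rule-based ADMET gating, and (when network inputs are
given) the systems-pharmacology overlap — writing each stage's output as a
plain CSV/JSON file so any stage can be re-run standalone, plus a
machine-readable run report with the per-stage funnel counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import admet, chem_space, compounds, similarity, syspharm

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and thresholds of one screening run.

    Defaults are the protocol's canonical values: cubic active curve,
    D_min < 0.2, mean Tanimoto > 0.7, and the standard gate rules.
    """

    structures: str = ""
    labels: str = ""
    out_dir: str = "screen_out"
    descriptor_provider: str = "rdkit2d"
    fingerprint_scheme: str = "path"
    fingerprint_depth: int = 4
    fingerprint_nbits: int = 2048
    n_components: int = 3
    degree: int = 3
    distance_threshold: float = 0.2
    similarity_threshold: float = 0.7
    admet_table: str | None = None
    gate_rules: dict = field(default_factory=dict)
    dti_tables: list[str] = field(default_factory=list)
    disease_lists: list[str] = field(default_factory=list)
    expression: str | None = None
    sample_meta: str | None = None
    tissue: str | None = None
    tissue_list: str | None = None  # precomputed tissue-specific gene list
    annotation_gmt: str | None = None
    enrichment_q_max: float = 0.01
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict[str, int]
    final_candidates: list[str]
    config_hash: str
    timing_s: float
    stages_run: list[str]
    overlap: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def run_screen(cfg: RunConfig) -> RunReport:
    """Execute the screening funnel; returns the run report.

    Stage order: compounds -> descriptors/PCA -> boundary -> distance ->
    similarity -> gate -> networks.  A hard error in any stage aborts with
    :class:`StageError`; outputs of completed stages stay on disk.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stages: list[str] = []

    def stage(name: str):
        stages.append(name)
        logger.info("stage: %s", name)

    try:
        stage("compounds")
        cs = compounds.load_compounds(cfg.structures, cfg.labels)
        cs.to_smi(out / "standardized.smi")
        counts["loaded"] = cs.provenance["n_read"]
        counts["unique"] = len(cs)
        actives = cs.by_role("known_active")
        unknowns = cs.by_role("unknown")
        counts["known_active"] = len(actives)
        counts["unknown"] = len(unknowns)
    except Exception as e:
        raise StageError("compounds", e) from e

    try:
        stage("chem_space")
        dm = compounds.compute_descriptors(cs, cfg.descriptor_provider)
        dm.values.to_csv(out / "descriptors.csv")
        labels = pd.Series({r.id: r.role for r in cs})
        model, _ = chem_space.fit_chem_space(
            dm, labels, n_components=cfg.n_components, degree=cfg.degree,
            threshold=cfg.distance_threshold,
        )
        (out / "chem_space_model.json").write_text(json.dumps(model.to_dict()))
        unk_X = dm.values.loc[unknowns.ids].to_numpy()
        table = model.screen(unk_X, unknowns.ids)
        table.to_csv(out / "distance_screen.csv", index=False)
        counts["in_box"] = int(table["in_box"].sum())
        counts["distance_significant"] = int(table["significant"].sum())
        dist_pass = table.loc[table["significant"], "id"].tolist()
    except Exception as e:
        raise StageError("chem_space", e) from e

    try:
        stage("similarity")
        known_fps = compounds.compute_fingerprints(
            actives, cfg.fingerprint_scheme, cfg.fingerprint_depth,
            cfg.fingerprint_nbits,
        )
        cand_set = unknowns.subset(dist_pass)
        if len(cand_set):
            cand_fps = compounds.compute_fingerprints(
                cand_set, cfg.fingerprint_scheme, cfg.fingerprint_depth,
                cfg.fingerprint_nbits,
            )
            ranked = similarity.prioritize(
                similarity.similarity_matrix(cand_fps, known_fps),
                threshold=cfg.similarity_threshold,
            )
        else:
            ranked = pd.DataFrame(columns=["id", "mean_similarity", "passes"])
        ranked.to_csv(out / "similarity.csv", index=False)
        counts["similarity_passing"] = int(ranked["passes"].sum()) if len(ranked) else 0
        sim_pass = ranked.loc[ranked["passes"], "id"].tolist() if len(ranked) else []
    except Exception as e:
        raise StageError("similarity", e) from e

    final = sim_pass
    try:
        if cfg.admet_table:
            stage("admet_gate")
            adf = pd.read_csv(cfg.admet_table)
            adf = adf[adf["id"].isin(sim_pass)] if sim_pass else adf.iloc[:0]
            rules = admet.RuleConfig(**cfg.gate_rules)
            verdicts, summary = admet.gate_table(adf, rules)
            verdicts.to_csv(out / "gate_verdicts.csv", index=False)
            counts["gate_passing"] = summary["n_pass"]
            final = summary["pass_ids"]
    except Exception as e:
        raise StageError("admet_gate", e) from e

    overlap_dict = None
    try:
        if cfg.dti_tables:
            stage("syspharm")
            tables = [pd.read_csv(p, sep="\t") for p in cfg.dti_tables]
            dti = syspharm.merge_dti_sources(tables)
            syspharm.write_network_tsv(dti, out / "dti_network")
            targets = set(dti["gene_symbol"])
            disease = syspharm.build_gene_set(
                {p: syspharm.read_gene_list(p) for p in cfg.disease_lists},
                name="disease",
            ) if cfg.disease_lists else syspharm.GeneSet("disease", frozenset())
            if cfg.tissue_list:
                tissue_set = syspharm.GeneSet(
                    "tissue", frozenset(
                        syspharm.normalize_symbol(g)
                        for g in syspharm.read_gene_list(cfg.tissue_list)
                    ),
                )
            elif cfg.expression and cfg.tissue:
                expr = pd.read_csv(cfg.expression, index_col=0)
                meta = pd.read_csv(cfg.sample_meta).set_index("sample")["tissue"]
                tissue_set = syspharm.tissue_specific_network(
                    expr, meta, cfg.tissue
                )
            else:
                tissue_set = syspharm.GeneSet("tissue", frozenset())
            report = syspharm.overlap_report(targets, disease, tissue_set)
            overlap_dict = report.to_dict()
            (out / "overlap.json").write_text(json.dumps(overlap_dict, indent=2))
            if cfg.annotation_gmt:
                ann = syspharm.read_gmt(cfg.annotation_gmt)
                universe = targets | disease.members | tissue_set.members
                hits = set(report.t_and_union)
                enr = syspharm.enrich(hits, ann, universe, cfg.enrichment_q_max)
                enr.to_csv(out / "enrichment.csv", index=False)
    except Exception as e:
        raise StageError("syspharm", e) from e

    report = RunReport(
        counts=counts,
        final_candidates=sorted(final),
        config_hash=cfg.config_hash(),
        timing_s=round(time.time() - t0, 3),
        stages_run=stages,
        overlap=overlap_dict,
    )
    report.to_json(out / "report.json")
    return report
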