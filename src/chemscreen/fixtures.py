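"""Deterministic synthetic fixtures for every screening stage.

Real inputs to this protocol (a curated natural-product family, GTEx-style
expression, predicted drug-target tables) are large downloads; these
generators produce small, structurally faithful stand-ins with *planted*
ground truth so each stage's recovery can be checked exactly:

- a compound family built by decorating a rigid polycyclic scaffold
  (adamantane) with polyol substituents, so the actives cluster in
  descriptor space the way a saponin family does, plus dissimilar-scaffold
  outliers;
- chemical-space score points planted at known distances to a fixed cubic
  active curve, inside/outside the actives' bounding box;
- fingerprint bit sets with a shared core so mean-Tanimoto pass/fail
  membership is known by construction;
- an expression matrix with planted tissue-specific and low-expression
  genes;
- drug-target / disease / tissue gene tables with planted overlap counts.

Everything is a pure function of the plan's single integer seed.  Default
plan sizes mirror the study conditions this protocol was designed around:
16 known actives among 98 unique compounds, 15 boundary outliers, 22
near-curve candidates of which 10 pass the similarity screen, a 500-gene ×
6-tissue expression matrix with 25 planted specific genes, and a 222-target
network overlapping a 124-gene disease set in 3 genes and a 907-gene
tissue-specific set in 13.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_space import ActiveCurve
from .compounds import Fingerprint


@dataclass(frozen=True)
class ExpressionPlan:
    n_genes: int = 500
    n_tissues: int = 6
    samples_per_tissue: int = 20
    n_specific: int = 25
    n_low_expression: int = 25
    baseline_mean: float = 5.0
    effect_size: float = 10.0  # fold change of the planted tissue mean
    tissue: str = "skin"

    def validate(self):
        if self.n_tissues < 2:
            raise ValueError("need >= 2 tissues")
        if self.n_specific + self.n_low_expression > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")


@dataclass(frozen=True)
class NetworkPlan:
    n_targets: int = 222
    n_disease: int = 124
    n_tissue: int = 907
    overlap_disease: int = 3
    overlap_tissue: int = 13
    overlap_both: int = 0
    drug_id: str = "CMPD-1"

    def validate(self):
        if self.overlap_both > min(self.overlap_disease, self.overlap_tissue):
            raise ValueError("triple overlap exceeds pairwise overlaps")
        if self.overlap_disease > min(self.n_targets, self.n_disease):
            raise ValueError("disease overlap exceeds set sizes")
        if self.overlap_tissue > min(self.n_targets, self.n_tissue):
            raise ValueError("tissue overlap exceeds set sizes")
        in_t = self.overlap_disease + self.overlap_tissue - self.overlap_both
        if in_t > self.n_targets:
            raise ValueError("planted overlaps exceed target count")


@dataclass(frozen=True)
class FixturePlan:
    seed: int = 0
    n_actives: int = 16
    n_unknowns: int = 82
    n_out_of_box: int = 15
    n_planted_near_curve: int = 22
    n_similar: int = 10
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    network: NetworkPlan = field(default_factory=NetworkPlan)

    def validate(self):
        if self.n_out_of_box + self.n_planted_near_curve > self.n_unknowns:
            raise ValueError("planted point counts exceed n_unknowns")
        if self.n_similar > self.n_planted_near_curve:
            raise ValueError("n_similar exceeds the near-curve candidate pool")
        if min(self.n_actives, self.n_unknowns) < 1 or self.seed < 0:
            raise ValueError("invalid plan")
        self.expression.validate()
        self.network.validate()

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "FixturePlan":
        d = dict(d)
        if "expression" in d:
            d["expression"] = ExpressionPlan(**d["expression"])
        if "network" in d:
            d["network"] = NetworkPlan(**d["network"])
        return cls(**d)


# ---------------------------------------------------------------------------
# compounds

_SCAFFOLD = "[*:1]C12CC3CC(CC(C3)C1)C2"  # 1-substituted adamantane

#: chain-extending substituent units; polyol-rich units mimic glycoside arms
_ACTIVE_UNITS = ["C(O)", "C(CO)"]
_UNKNOWN_UNITS = ["C(O)", "C", "C(CO)", "C(N)"]

_OUTLIER_SMILES = [
    "c1ccccc1", "c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
    "CCCCCCCCCCCCCCCC", "C=CC=CC=CC=C", "c1ccncc1",
    "c1ccc2[nH]ccc2c1", "O=C(O)c1ccccc1", "Nc1ccccc1",
    "Clc1ccccc1Cl", "FC(F)(F)c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O",
    "c1ccsc1", "c1ccoc1", "C#CC#CC#C", "OCCOCCOCCO",
    "CC(C)CC(C)(C)C", "N#Cc1ccccc1", "COc1ccc(OC)cc1", "CCCCOC(=O)CCC",
]


def _decorated_smiles(units: list[str], rng: np.random.Generator,
                      min_len: int, max_len: int) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    arm = "".join(rng.choice(units) for _ in range(n))
    sub = Chem.MolFromSmiles(f"[*:1]O{arm}")
    core = Chem.MolFromSmiles(_SCAFFOLD)
    return Chem.MolToSmiles(Chem.molzip(core, sub))


def make_compound_fixture(plan: FixturePlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic compound collection: (structures, labels) tables.

    Structures: columns ``id, smiles``; labels: ``id, role, name``.  The
    actives and most unknowns share the decorated-adamantane family; the
    last ``n_out_of_box`` unknowns use dissimilar scaffolds and are
    expected to fall outside the actives' descriptor-space bounding box.
    All SMILES parse and standardize cleanly with no duplicate InChIKeys.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    n_family_unknowns = plan.n_unknowns - plan.n_out_of_box
    if plan.n_out_of_box > len(_OUTLIER_SMILES):
        raise ValueError(
            f"at most {len(_OUTLIER_SMILES)} outlier scaffolds available"
        )

    seen: set[str] = set()
    rows: list[tuple[str, str, str]] = []

    def add(smiles: str, role: str, prefix: str) -> bool:
        mol = Chem.MolFromSmiles(smiles)
        ikey = Chem.MolToInchiKey(mol)
        if ikey in seen:
            return False
        seen.add(ikey)
        rows.append((f"{prefix}{len(rows) + 1:03d}", smiles, role))
        return True

    guard = 0
    while sum(1 for r in rows if r[2] == "known_active") < plan.n_actives:
        add(_decorated_smiles(_ACTIVE_UNITS, rng, 4, 6), "known_active", "CPD")
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not generate enough unique actives")
    while len(rows) < plan.n_actives + n_family_unknowns:
        add(_decorated_smiles(_UNKNOWN_UNITS, rng, 3, 7), "unknown", "CPD")
        guard += 1
        if guard > 20000:
            raise RuntimeError("could not generate enough unique unknowns")
    for smi in _OUTLIER_SMILES[: plan.n_out_of_box]:
        add(smi, "unknown", "CPD")

    structures = pd.DataFrame(
        {"id": [r[0] for r in rows], "smiles": [r[1] for r in rows]}
    )
    labels = pd.DataFrame(
        {
            "id": [r[0] for r in rows],
            "role": [r[2] for r in rows],
            "name": [f"synthetic-{r[0]}" for r in rows],
        }
    )
    return structures, labels


# ---------------------------------------------------------------------------
# chemical-space points

#: fixed cubic active curve used by the point fixture: y = 1 - 0.5 x + 0.1 x^3
FIXTURE_CURVE = ActiveCurve((1.0, -0.5, 0.0, 0.1), (-2.0, 2.0))


def _dense_distance(curve: ActiveCurve, q: np.ndarray, n: int = 20001) -> float:
    xs = np.linspace(curve.domain[0], curve.domain[1], n)
    ys = curve(xs)
    return float(np.sqrt((xs - q[0]) ** 2 + (ys - q[1]) ** 2).min())


def make_chemspace_fixture(plan: FixturePlan) -> dict:
    """Planted score points around a fixed cubic active curve.

    Returns ``active_points`` (n_actives × pc1..pc3 on the curve),
    ``unknown_points`` (id, pc1..pc3), and ``truth`` labelling each unknown
    ``near`` (distance to curve < 0.2, in box), ``far`` (in box, distance
    >= 0.25) or ``out_of_box``.  Placement is verified against a dense
    sampling of the curve at generation time, so stage recovery is exact
    by construction.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed + 1)
    curve = FIXTURE_CURVE
    lo, hi = curve.domain

    ax = np.linspace(lo, hi, plan.n_actives)
    az = rng.uniform(-1.0, 1.0, plan.n_actives)
    az[0], az[1] = -1.0, 1.0  # pin the pc3 box to a known range
    active = np.column_stack([ax, curve(ax), az])
    mins, maxs = active.min(axis=0), active.max(axis=0)

    def in_box(q3: np.ndarray) -> bool:
        return bool(np.all(q3 >= mins) and np.all(q3 <= maxs))

    pts: list[np.ndarray] = []
    kinds: list[str] = []

    while sum(k == "near" for k in kinds) < plan.n_planted_near_curve:
        x = rng.uniform(lo + 0.2, hi - 0.2)
        theta = rng.uniform(0, 2 * np.pi)
        q = np.array([x, float(curve(x))]) + 0.1 * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        q3 = np.append(q, rng.uniform(-0.9, 0.9))
        if in_box(q3) and _dense_distance(curve, q) < 0.18:
            pts.append(q3)
            kinds.append("near")

    n_far = plan.n_unknowns - plan.n_planted_near_curve - plan.n_out_of_box
    while sum(k == "far" for k in kinds) < n_far:
        q = np.array([rng.uniform(mins[0], maxs[0]), rng.uniform(mins[1], maxs[1])])
        q3 = np.append(q, rng.uniform(-0.9, 0.9))
        if in_box(q3) and _dense_distance(curve, q) >= 0.25:
            pts.append(q3)
            kinds.append("far")

    for i in range(plan.n_out_of_box):
        q3 = np.array([
            rng.uniform(mins[0], maxs[0]),
            rng.uniform(mins[1], maxs[1]),
            rng.uniform(-0.9, 0.9),
        ])
        q3[i % 3] = (maxs if i % 2 == 0 else mins)[i % 3] + (
            rng.uniform(0.5, 1.5) if i % 2 == 0 else -rng.uniform(0.5, 1.5)
        )
        pts.append(q3)
        kinds.append("out_of_box")

    order = rng.permutation(len(pts))
    ids = [f"U{i + 1:03d}" for i in range(len(pts))]
    unknown = pd.DataFrame(
        np.array(pts)[order], columns=["pc1", "pc2", "pc3"]
    )
    unknown.insert(0, "id", ids)
    truth = pd.DataFrame({"id": ids, "planted": np.array(kinds)[order]})
    return {
        "curve": curve,
        "active_points": pd.DataFrame(active, columns=["pc1", "pc2", "pc3"]),
        "unknown_points": unknown,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# fingerprints

def make_fingerprint_fixture(plan: FixturePlan, nbits: int = 2048) -> dict:
    """Bit-set fingerprints with planted high-similarity analogues.

    Knowns share a 120-bit core plus 10 private bits each; ``n_similar``
    unknowns reuse the core (mean Tanimoto to the panel >= 120/138 > 0.7 by
    construction), the rest draw bits disjoint from every known (mean 0).
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed + 2)
    scheme = "synthetic:fixture"
    all_bits = rng.permutation(nbits)
    core = frozenset(int(b) for b in all_bits[:120])
    private_pool = [int(b) for b in all_bits[120:600]]
    disjoint_pool = [int(b) for b in all_bits[600:]]

    def take(pool: list[int], k: int) -> frozenset[int]:
        idx = rng.choice(len(pool), size=k, replace=False)
        return frozenset(pool[i] for i in idx)

    knowns = [
        Fingerprint(f"K{i + 1:03d}", core | take(private_pool, 10), nbits, scheme)
        for i in range(plan.n_actives)
    ]
    unknowns = []
    kinds = []
    for i in range(plan.n_similar):
        unknowns.append(
            Fingerprint(f"U{i + 1:03d}", core | take(private_pool, 8), nbits, scheme)
        )
        kinds.append("similar")
    for i in range(plan.n_similar, plan.n_planted_near_curve):
        unknowns.append(
            Fingerprint(f"U{i + 1:03d}", take(disjoint_pool, 100), nbits, scheme)
        )
        kinds.append("dissimilar")
    truth = pd.DataFrame(
        {"id": [u.compound_id for u in unknowns], "planted": kinds}
    )
    return {"knowns": knowns, "unknowns": unknowns, "truth": truth}


# ---------------------------------------------------------------------------
# expression

def make_expression_fixture(plan: FixturePlan) -> dict:
    """RPKM-scale matrix with planted tissue-specific / low-expression genes.

    Baseline genes are log-normal around ``baseline_mean`` independently in
    every sample.  Planted specific genes are nearly constant within each
    tissue with the target tissue raised ``effect_size``-fold — the
    one-high-tissue configuration whose Z across per-tissue means
    approaches the attainable maximum (n_tissues - 1)/sqrt(n_tissues), so
    the planted flag exceeds Z > 2 for any seed when n_tissues >= 6.
    Planted low-expression genes sit below RPKM 1 in every sample.
    """
    ep = plan.expression
    ep.validate()
    rng = np.random.default_rng(plan.seed + 3)
    tissues = [ep.tissue] + [f"tissue{i + 2}" for i in range(ep.n_tissues - 1)]
    samples = []
    tissue_of = {}
    for t in tissues:
        for j in range(ep.samples_per_tissue):
            sid = f"{t}_s{j + 1:02d}"
            samples.append(sid)
            tissue_of[sid] = t
    n_samples = len(samples)

    genes = [f"GENE{i + 1:04d}" for i in range(ep.n_genes)]
    vals = rng.lognormal(mean=np.log(ep.baseline_mean), sigma=0.5,
                         size=(ep.n_genes, n_samples))

    gene_idx = rng.permutation(ep.n_genes)
    spec_idx = gene_idx[: ep.n_specific]
    low_idx = gene_idx[ep.n_specific: ep.n_specific + ep.n_low_expression]

    target_cols = np.array([tissue_of[s] == ep.tissue for s in samples])

    # The fixture's contract is exact ground truth: no baseline gene may sit
    # near the Z cutoff by chance, so rows whose target-tissue Z across
    # per-tissue means would exceed 1.9 are redrawn.
    tissue_cols = {t: np.array([tissue_of[s] == t for s in samples]) for t in tissues}

    def target_z(rows: np.ndarray) -> np.ndarray:
        tm = np.column_stack([rows[:, c].mean(axis=1) for c in tissue_cols.values()])
        sd = tm.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore"):
            return np.where(sd > 0, (tm[:, 0] - tm.mean(axis=1)) / sd, 0.0)

    for _ in range(100):
        bad = np.flatnonzero(target_z(vals) > 1.9)
        if bad.size == 0:
            break
        vals[bad] = rng.lognormal(np.log(ep.baseline_mean), 0.5,
                                  size=(bad.size, n_samples))
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a clean baseline matrix")
    for gi in spec_idx:
        base = ep.baseline_mean
        row = base * (1 + rng.normal(0, 1e-3, n_samples))
        row[target_cols] = base * ep.effect_size * (1 + rng.normal(0, 1e-3, target_cols.sum()))
        vals[gi] = np.abs(row)
    for gi in low_idx:
        vals[gi] = rng.uniform(0.05, 0.8, n_samples)

    expr = pd.DataFrame(vals, index=genes, columns=samples)
    meta = pd.DataFrame({"sample": samples,
                         "tissue": [tissue_of[s] for s in samples]})
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted_specific": [i in set(spec_idx) for i in range(ep.n_genes)],
            "planted_low": [i in set(low_idx) for i in range(ep.n_genes)],
        }
    ).set_index("gene")
    return {"expression": expr, "samples": meta, "truth": truth}


# ---------------------------------------------------------------------------
# networks

def make_network_fixture(plan: FixturePlan) -> dict:
    """DTI tables + disease/tissue gene sets with planted overlap counts.

    The merged drug-target network has exactly ``n_targets`` unique
    (drug, gene) pairs (raw tables include duplicate and non-human rows to
    exercise the merge); ``overlap_report`` on the generated sets returns
    exactly the planned |T∩D|, |T∩S| and triple-overlap counts.
    """
    np_plan = plan.network
    np_plan.validate()
    rng = np.random.default_rng(plan.seed + 4)

    n_total = (
        np_plan.n_targets
        + np_plan.n_disease
        + np_plan.n_tissue
    )
    pool = [f"GENE{i + 1:05d}" for i in range(n_total + 50)]
    rng.shuffle(pool)
    it = iter(pool)

    def draw(k: int) -> list[str]:
        return [next(it) for _ in range(k)]

    g_both = draw(np_plan.overlap_both)
    g_td = draw(np_plan.overlap_disease - np_plan.overlap_both)
    g_ts = draw(np_plan.overlap_tissue - np_plan.overlap_both)
    n_t_priv = (np_plan.n_targets - np_plan.overlap_disease
                - np_plan.overlap_tissue + np_plan.overlap_both)
    t_priv = draw(n_t_priv)
    d_priv = draw(np_plan.n_disease - np_plan.overlap_disease)
    s_priv = draw(np_plan.n_tissue - np_plan.overlap_tissue)

    targets = g_both + g_td + g_ts + t_priv
    disease = g_both + g_td + d_priv
    tissue = g_both + g_ts + s_priv

    # three source tables; rows cycle sources, plus planted noise rows
    rows = []
    for i, g in enumerate(targets):
        rows.append((np_plan.drug_id, g, DTI_SOURCES_CYCLE[i % 3], "Homo sapiens"))
    dup_idx = rng.choice(len(targets), size=min(5, len(targets)), replace=False)
    for i in dup_idx:  # duplicate pairs from a different source
        g = targets[i]
        rows.append((np_plan.drug_id, g,
                     DTI_SOURCES_CYCLE[(i + 1) % 3], "Homo sapiens"))
    for g in draw(5):  # non-human rows, dropped by the merge
        rows.append((np_plan.drug_id, g, "literature", "Mus musculus"))

    df = pd.DataFrame(rows, columns=["drug_id", "gene", "source", "organism"])
    tables = [df[df["source"] == s].reset_index(drop=True) for s in DTI_SOURCES_CYCLE]

    # overlapping disease source lists whose union is exactly `disease`
    k = len(disease)
    quarters = [disease[: k // 2], disease[k // 4: 3 * k // 4],
                disease[k // 2:], disease[:: 7] or disease[:1]]
    disease_sources = {f"source_{i + 1}": q for i, q in enumerate(quarters)}

    return {
        "dti_tables": tables,
        "disease_sources": disease_sources,
        "tissue_genes": sorted(tissue),
        "truth": {
            "n_targets": np_plan.n_targets,
            "n_disease": np_plan.n_disease,
            "n_tissue": np_plan.n_tissue,
            "targets_in_disease": np_plan.overlap_disease,
            "targets_in_tissue": np_plan.overlap_tissue,
            "targets_in_both": np_plan.overlap_both,
            "targets_in_union": (np_plan.overlap_disease + np_plan.overlap_tissue
                                 - np_plan.overlap_both),
        },
    }


DTI_SOURCES_CYCLE = ("docking", "literature", "network_prediction")


# ---------------------------------------------------------------------------
# bundle writer

def write_fixture_bundle(plan: FixturePlan, out_dir: str | Path) -> dict[str, str]:
    """Write every fixture as plain-text files; returns the path map."""
    from .compounds import fingerprints_to_csv  # local import avoids cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    structures, labels = make_compound_fixture(plan)
    smi = out / "compounds.smi"
    with open(smi, "w") as fh:
        for _, r in structures.iterrows():
            fh.write(f"{r['smiles']} {r['id']}\n")
    labels.to_csv(out / "labels.csv", index=False)
    paths["structures"] = str(smi)
    paths["labels"] = str(out / "labels.csv")

    cf = make_chemspace_fixture(plan)
    cf["active_points"].to_csv(out / "active_points.csv", index=False)
    cf["unknown_points"].to_csv(out / "unknown_points.csv", index=False)
    cf["truth"].to_csv(out / "points_truth.csv", index=False)
    paths["unknown_points"] = str(out / "unknown_points.csv")

    ff = make_fingerprint_fixture(plan)
    fingerprints_to_csv(ff["knowns"], out / "known_fps.csv")
    fingerprints_to_csv(ff["unknowns"], out / "unknown_fps.csv")
    ff["truth"].to_csv(out / "fps_truth.csv", index=False)
    paths["known_fps"] = str(out / "known_fps.csv")
    paths["unknown_fps"] = str(out / "unknown_fps.csv")

    ef = make_expression_fixture(plan)
    ef["expression"].to_csv(out / "expression.csv")
    ef["samples"].to_csv(out / "samples.csv", index=False)
    ef["truth"].to_csv(out / "expression_truth.csv")
    paths["expression"] = str(out / "expression.csv")
    paths["samples"] = str(out / "samples.csv")

    nf = make_network_fixture(plan)
    for i, t in enumerate(nf["dti_tables"]):
        p = out / f"dti_{DTI_SOURCES_CYCLE[i]}.tsv"
        t.to_csv(p, sep="\t", index=False)
        paths[f"dti_{DTI_SOURCES_CYCLE[i]}"] = str(p)
    for name, genes in nf["disease_sources"].items():
        p = out / f"disease_{name}.txt"
        p.write_text("\n".join(genes) + "\n")
        paths[f"disease_{name}"] = str(p)
    (out / "tissue_genes.txt").write_text("\n".join(nf["tissue_genes"]) + "\n")
    paths["tissue_genes"] = str(out / "tissue_genes.txt")
    return paths
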