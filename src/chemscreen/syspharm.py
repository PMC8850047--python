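"""Drug–target, disease-gene and tissue-specific network integration.

This module assembles the three gene/protein sets a systems-pharmacology
read-out needs — the predicted target set of a candidate compound, a
curated disease gene set, and the genes specifically expressed in the
disease-relevant tissue — and intersects them.  Tissue specificity follows
the standard Z-expression score: for gene *i* and tissue *t*,

    Z(E(i,t)) = (E(i,t) - E(i)) / sd_E(i)

where ``E(i,t)`` is the gene's mean expression in tissue *t* and
``E(i)``/``sd_E(i)`` are, by default, the mean and standard deviation of
the per-tissue means across all tissues (an "across samples" reference is
available by flag).  A gene is *expressed* in the tissue when its RPKM is
at least 1 in more than 80% of that tissue's samples, and *specific* when
it is expressed and Z > 2 (both strict).

Overlap counts against the disease and tissue sets, and hypergeometric
enrichment with Holm (step-down Bonferroni) correction against a
user-supplied GMT annotation, complete the workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DTI_SOURCES = ("docking", "literature", "network_prediction")


def normalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Uppercase/strip a gene symbol and resolve it through an alias map."""
    s = str(symbol).strip().upper()
    if alias_map:
        s = alias_map.get(s, s)
    return s


@dataclass
class GeneSet:
    """A named set of normalized human gene symbols with provenance."""

    name: str
    members: frozenset[str]
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, g: str) -> bool:
        return g in self.members


@dataclass(frozen=True)
class OverlapReport:
    """Intersections of a target set with disease and tissue gene sets."""

    targets: frozenset[str]
    disease: frozenset[str]
    tissue: frozenset[str]

    @property
    def t_and_d(self) -> list[str]:
        return sorted(self.targets & self.disease)

    @property
    def t_and_s(self) -> list[str]:
        return sorted(self.targets & self.tissue)

    @property
    def t_and_d_and_s(self) -> list[str]:
        return sorted(self.targets & self.disease & self.tissue)

    @property
    def t_and_union(self) -> list[str]:
        return sorted(self.targets & (self.disease | self.tissue))

    def counts(self) -> dict[str, int]:
        return {
            "n_targets": len(self.targets),
            "n_disease": len(self.disease),
            "n_tissue": len(self.tissue),
            "targets_in_disease": len(self.t_and_d),
            "targets_in_tissue": len(self.t_and_s),
            "targets_in_both": len(self.t_and_d_and_s),
            "targets_in_union": len(self.t_and_union),
        }

    def to_dict(self) -> dict:
        return {
            **self.counts(),
            "members": {
                "targets_in_disease": self.t_and_d,
                "targets_in_tissue": self.t_and_s,
                "targets_in_both": self.t_and_d_and_s,
                "targets_in_union": self.t_and_union,
            },
        }


# ---------------------------------------------------------------------------
# drug-target network assembly


def merge_dti_sources(
    tables: Sequence[pd.DataFrame],
    alias_map: Mapping[str, str] | None = None,
    human_only: bool = True,
    on_unmapped: str = "drop",
) -> pd.DataFrame:
    """Merge drug–target tables into one deduplicated human DTI edge list.

    Each table needs columns ``drug_id, gene, source`` and optionally
    ``organism``; rows whose organism is present and not Homo sapiens are
    dropped (logged) when ``human_only``.  Symbols are normalized through
    ``alias_map``; (drug, gene) duplicates are merged keeping the union of
    sources.  ``on_unmapped='error'`` turns empty/unmappable symbols into a
    hard failure instead of a logged drop.
    """
    frames = []
    for t in tables:
        need = {"drug_id", "gene", "source"}
        if not need.issubset(t.columns):
            raise ValueError(f"DTI table missing columns {need - set(t.columns)}")
        frames.append(t.copy())
    if not frames:
        return pd.DataFrame(columns=["drug_id", "gene_symbol", "sources"])
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        return pd.DataFrame(columns=["drug_id", "gene_symbol", "sources"])

    if human_only and "organism" in df.columns:
        org = df["organism"].fillna("Homo sapiens").str.strip().str.lower()
        keep = org.isin({"homo sapiens", "human", "9606"})
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d non-human DTI rows", n_drop)
        df = df[keep]

    df["gene_symbol"] = df["gene"].map(lambda g: normalize_symbol(g, alias_map))
    bad = df["gene_symbol"] == ""
    if bad.any():
        if on_unmapped == "error":
            raise ValueError(f"{int(bad.sum())} unmappable gene symbols")
        logger.warning("dropping %d rows with empty gene symbols", int(bad.sum()))
        df = df[~bad]

    merged = (
        df.groupby(["drug_id", "gene_symbol"], sort=True)["source"]
        .apply(lambda s: ";".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"source": "sources"})
    )
    return merged


def build_gene_set(
    sources: Mapping[str, Iterable[str]],
    alias_map: Mapping[str, str] | None = None,
    name: str = "gene_set",
) -> GeneSet:
    """Union of normalized gene lists, preserving per-member provenance."""
    members: set[str] = set()
    provenance: list[str] = []
    for src_name, genes in sources.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"source {src_name!r} is empty")
        provenance.append(src_name)
        members |= {normalize_symbol(g, alias_map) for g in genes}
    members.discard("")
    return GeneSet(name=name, members=frozenset(members), sources=provenance)


# ---------------------------------------------------------------------------
# tissue-specific expression


def tissue_specificity(
    expr: pd.DataFrame,
    tissue_labels: pd.Series | Mapping[str, str],
    tissue: str,
    expr_min: float = 1.0,
    expr_frac: float = 0.8,
    z_min: float = 2.0,
    reference: str = "tissues",
) -> pd.DataFrame:
    """Z-expression tissue specificity for every gene.

    Parameters
    ----------
    expr : genes × samples matrix of RPKM-scale values (non-negative).
    tissue_labels : sample -> tissue assignment covering every column.
    tissue : the tissue of interest (must be present; >= 2 tissues total).
    expr_min, expr_frac : a gene is *expressed* when its value is
        >= ``expr_min`` in strictly more than ``expr_frac`` of the tissue's
        samples.
    z_min : specificity requires Z strictly greater than this.
    reference : "tissues" computes E(i)/sd over per-tissue means (default);
        "samples" computes them over all samples directly.

    Returns a per-gene table with columns ``tissue_mean, mean_overall,
    sd_overall, z, expressed, specific, reason``.  Genes with zero
    reference sd get an undefined Z (NaN) and are non-specific with reason
    ``"sd_zero"``.
    """
    labels = pd.Series(tissue_labels).reindex(expr.columns)
    if labels.isna().any():
        missing = list(expr.columns[labels.isna()])
        raise ValueError(f"samples without tissue label: {missing[:5]}")
    tissues = labels.unique()
    if tissue not in set(tissues):
        raise ValueError(f"tissue {tissue!r} not present in labels")
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues for a specificity reference")
    vals = expr.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")

    in_t = (labels == tissue).to_numpy()
    tissue_mean = expr.loc[:, in_t].mean(axis=1)

    per_tissue_means = pd.DataFrame(
        {t: expr.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in tissues}
    )
    if reference == "tissues":
        mean_overall = per_tissue_means.mean(axis=1)
        sd_overall = per_tissue_means.std(axis=1, ddof=1)
    elif reference == "samples":
        mean_overall = expr.mean(axis=1)
        sd_overall = expr.std(axis=1, ddof=1)
    else:
        raise ValueError("reference must be 'tissues' or 'samples'")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (tissue_mean - mean_overall) / sd_overall
    z = z.where(sd_overall > 0)

    frac_expressed = (expr.loc[:, in_t] >= expr_min).mean(axis=1)
    expressed = frac_expressed > expr_frac
    specific = expressed & (z > z_min) & sd_overall.gt(0)

    reason = pd.Series("", index=expr.index, dtype=object)
    reason[~expressed] = "not_expressed"
    reason[expressed & sd_overall.le(0)] = "sd_zero"
    reason[expressed & sd_overall.gt(0) & ~(z > z_min)] = "low_z"

    return pd.DataFrame(
        {
            "tissue_mean": tissue_mean,
            "mean_overall": mean_overall,
            "sd_overall": sd_overall,
            "z": z,
            "expressed": expressed,
            "specific": specific,
            "reason": reason,
        }
    )


def tissue_specific_network(
    expr: pd.DataFrame,
    tissue_labels: pd.Series | Mapping[str, str],
    tissue: str,
    **kwargs,
) -> GeneSet:
    """GeneSet of tissue-specific genes (see :func:`tissue_specificity`)."""
    table = tissue_specificity(expr, tissue_labels, tissue, **kwargs)
    return GeneSet(
        name=f"{tissue}_specific",
        members=frozenset(table.index[table["specific"]]),
        sources=[f"tissue_specificity({tissue})"],
    )


# ---------------------------------------------------------------------------
# overlap + enrichment


def overlap_report(
    targets: GeneSet | Iterable[str],
    disease: GeneSet | Iterable[str],
    tissue_specific: GeneSet | Iterable[str],
) -> OverlapReport:
    """Exact set intersections of targets with disease and tissue networks."""
    as_set = lambda s: frozenset(s.members if isinstance(s, GeneSet) else s)
    return OverlapReport(as_set(targets), as_set(disease), as_set(tissue_specific))


def enrich(
    hits: GeneSet | Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: GeneSet | Iterable[str],
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in annotation terms.

    For a universe of size N, a term of size K (after intersection with the
    universe) and n hits of which k fall in the term, the raw p-value is
    the upper tail P(X >= k) of Hypergeom(N, K, n).  Holm's step-down
    Bonferroni correction gives q; terms with q < ``q_max`` are returned,
    sorted by q then raw p.
    """
    hit_set = frozenset(hits.members if isinstance(hits, GeneSet) else hits)
    uni = frozenset(universe.members if isinstance(universe, GeneSet) else universe)
    if not uni:
        raise ValueError("empty universe")
    if not hit_set <= uni:
        raise ValueError(f"hits outside universe: {sorted(hit_set - uni)[:5]}")

    rows = []
    for term, genes in annotation.items():
        term_genes = frozenset(normalize_symbol(g) for g in genes) & uni
        if not term_genes:
            continue
        k = len(hit_set & term_genes)
        p = float(hypergeom.sf(k - 1, len(uni), len(term_genes), len(hit_set)))
        rows.append(
            {
                "term": term,
                "term_size": len(term_genes),
                "hits": k,
                "p": min(p, 1.0),
                "hit_members": ";".join(sorted(hit_set & term_genes)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["term", "term_size", "hits", "p", "q", "hit_members"])
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="holm")
    df["q"] = q
    df = df[df["q"] < q_max]
    return df.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)[
        ["term", "term_size", "hits", "p", "q", "hit_members"]
    ]


# ---------------------------------------------------------------------------
# file formats


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[parts[0]] = parts[2:]
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in terms.items():
            fh.write("\t".join([name, name, *sorted(set(genes))]) + "\n")


def write_network_tsv(dti: pd.DataFrame, out_prefix: str | Path) -> None:
    """Write node/edge TSVs loadable by standard graph viewers."""
    out_prefix = Path(out_prefix)
    dti.to_csv(out_prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    nodes = pd.DataFrame(
        {
            "node": pd.concat([dti["drug_id"], dti["gene_symbol"]]).unique(),
        }
    )
    nodes["kind"] = np.where(nodes["node"].isin(dti["drug_id"]), "drug", "target")
    nodes.to_csv(out_prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
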