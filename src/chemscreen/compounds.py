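"""Reading, standardization, and featurization of compound collections.

Compounds arrive as a SMILES list (``.smi``) or an SDF plus a label table
assigning each id the role ``known_active`` or ``unknown``.  Structures are
standardized (largest fragment, charge normalization, canonical SMILES with
stereochemistry preserved) and deduplicated by InChIKey, then featurized
either as a dense 2D descriptor matrix or as topological path fingerprints.

Descriptor sets and fingerprint schemes are pluggable through small
registries so that the screening protocol itself stays independent of any
particular (possibly proprietary) featurizer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

ROLES = ("known_active", "unknown")


class CompoundParseError(ValueError):
    """A structure failed to parse; carries the offending record index."""

    def __init__(self, message: str, record: int | None = None):
        super().__init__(message)
        self.record = record


@dataclass(frozen=True)
class CompoundRecord:
    """One standardized structure with identity keys and screening role."""

    id: str
    smiles: str
    inchikey: str
    role: str
    name: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey {self.inchikey!r} for {self.id!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # standardized SMILES should always round-trip
            raise CompoundParseError(f"stored SMILES unparseable for {self.id!r}")
        return m


@dataclass
class CompoundSet:
    """Ordered, InChIKey-deduplicated collection of compound records."""

    records: list[CompoundRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [r.inchikey for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate InChIKeys in CompoundSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "CompoundSet":
        wanted = set(ids)
        return CompoundSet(
            [r for r in self.records if r.id in wanted], dict(self.provenance)
        )

    def by_role(self, role: str) -> "CompoundSet":
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return CompoundSet(
            [r for r in self.records if r.role == role], dict(self.provenance)
        )

    def to_smi(self, path: str | Path) -> None:
        """Write ``smiles id`` lines plus a JSON provenance sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f"{r.smiles} {r.id}\n")
        sidecar = {
            "provenance": self.provenance,
            "roles": {r.id: r.role for r in self.records},
            "names": {r.id: r.name for r in self.records if r.name},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


@dataclass(frozen=True)
class Fingerprint:
    """A molecular fingerprint as a set of on-bit indices."""

    compound_id: str
    bits: frozenset[int]
    nbits: int
    scheme: str

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index out of range")


@dataclass
class DescriptorMatrix:
    """Dense per-compound descriptor table with a cleaning log.

    ``values`` is indexed by compound id with one column per descriptor.
    ``imputed`` records (compound_id, descriptor) cells that were non-finite
    and were replaced by the column mean; ``zero_variance`` flags constant
    columns (left in place — downstream consumers decide whether to drop).
    """

    values: pd.DataFrame
    provider: str
    imputed: list[tuple[str, str]] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("descriptor matrix contains non-finite entries")


# ---------------------------------------------------------------------------
# standardization

_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Standardize: largest fragment -> neutralize charges -> sanitize.

    Stereochemistry is preserved (epimeric natural products are distinct
    compounds); no tautomer canonicalization is applied.
    """
    mol = _largest_fragment.choose(mol)
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def standardize_smiles(smiles: str) -> tuple[str, str]:
    """Return (canonical SMILES, InChIKey) of the standardized structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundParseError(f"unparseable SMILES: {smiles!r}")
    mol = standardize_mol(mol)
    return Chem.MolToSmiles(mol), Chem.MolToInchiKey(mol)


# ---------------------------------------------------------------------------
# loading


def _read_structures(path: Path) -> list[tuple[str, Chem.Mol, int]]:
    """Yield (id, mol, line/record number) from a .smi or SDF file."""
    out: list[tuple[str, Chem.Mol, int]] = []
    suffix = path.suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise CompoundParseError(
                    f"{path.name}:{lineno}: unparseable SMILES {smiles!r}", lineno
                )
            out.append((cid, mol, lineno))
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                raise CompoundParseError(f"{path.name}: record {i + 1} unparseable", i + 1)
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
            out.append((cid, mol, i + 1))
    else:
        raise ValueError(f"unsupported structure format: {path.suffix!r}")
    return out


def load_compounds(
    path: str | Path,
    labels: str | Path | pd.DataFrame,
) -> CompoundSet:
    """Load, standardize and InChIKey-deduplicate a compound collection.

    Parameters
    ----------
    path : file with structures (``.smi`` whitespace-separated SMILES + id,
        or SDF V2000 with ids in the molecule name field).
    labels : CSV with header ``id,role,name`` (``name`` optional), or an
        equivalent DataFrame; every structure id must be present and the
        role must be ``known_active`` or ``unknown``.

    Duplicate structures (identical InChIKey after standardization) keep the
    first-seen record; collisions are logged as warnings.  An id present in
    the label table but absent from the structure file is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(labels, (str, Path)):
        labels = pd.read_csv(labels, dtype=str)
    if "id" not in labels.columns or "role" not in labels.columns:
        raise ValueError("label table must have columns id,role[,name]")
    label_map = labels.set_index("id")

    structures = _read_structures(path)
    struct_ids = {cid for cid, _, _ in structures}
    missing = [i for i in label_map.index if i not in struct_ids]
    if missing:
        raise ValueError(f"label ids absent from structure file: {missing}")

    records: list[CompoundRecord] = []
    seen: dict[str, str] = {}
    for cid, mol, recno in structures:
        if cid not in label_map.index:
            raise ValueError(f"structure id {cid!r} missing from label table")
        mol = standardize_mol(mol)
        smiles = Chem.MolToSmiles(mol)
        ikey = Chem.MolToInchiKey(mol)
        if ikey in seen:
            logger.warning(
                "duplicate structure: %s collides with %s (InChIKey %s); keeping first",
                cid, seen[ikey], ikey,
            )
            continue
        seen[ikey] = cid
        row = label_map.loc[cid]
        name = row.get("name")
        records.append(
            CompoundRecord(
                id=cid,
                smiles=smiles,
                inchikey=ikey,
                role=str(row["role"]),
                name=None if pd.isna(name) else str(name),
            )
        )
    provenance = {
        "source": str(path),
        "n_read": len(structures),
        "n_unique": len(records),
        "standardization": "largest_fragment+uncharge, stereo preserved",
    }
    return CompoundSet(records, provenance)


# ---------------------------------------------------------------------------
# descriptors

DescriptorProvider = Callable[[Chem.Mol], dict[str, float]]
DESCRIPTOR_PROVIDERS: dict[str, DescriptorProvider] = {}


def register_descriptor_provider(name: str, fn: DescriptorProvider) -> None:
    DESCRIPTOR_PROVIDERS[name] = fn


def _rdkit_2d(mol: Chem.Mol) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Descriptors.CalcMolDescriptors(mol)


register_descriptor_provider("rdkit2d", _rdkit_2d)


def compute_descriptors(cs: CompoundSet, provider: str = "rdkit2d") -> DescriptorMatrix:
    """Compute the full 2D descriptor table for a compound set.

    Non-finite cells (a descriptor failing on a particular molecule) are
    column-mean imputed and logged; constant (zero-variance) columns are
    flagged in the result but retained.
    """
    if provider not in DESCRIPTOR_PROVIDERS:
        raise ValueError(
            f"unknown descriptor provider {provider!r}; "
            f"registered: {sorted(DESCRIPTOR_PROVIDERS)}"
        )
    fn = DESCRIPTOR_PROVIDERS[provider]
    rows = {r.id: fn(r.mol()) for r in cs}
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df = df.loc[cs.ids]  # preserve input order

    imputed: list[tuple[str, str]] = []
    arr = df.to_numpy()
    bad = ~np.isfinite(arr)
    if bad.any():
        col_means = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        for i, j in zip(*np.where(bad)):
            imputed.append((df.index[i], df.columns[j]))
            logger.warning(
                "descriptor %s failed for %s; column-mean imputed",
                df.columns[j], df.index[i],
            )
        arr[bad] = np.broadcast_to(col_means, arr.shape)[bad]
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)

    zero_var = [c for c in df.columns if df[c].nunique() <= 1]
    return DescriptorMatrix(values=df, provider=provider, imputed=imputed,
                            zero_variance=zero_var)


# ---------------------------------------------------------------------------
# fingerprints

FingerprintScheme = Callable[[Chem.Mol, int, int], frozenset[int]]
FINGERPRINT_SCHEMES: dict[str, FingerprintScheme] = {}


def register_fingerprint_scheme(name: str, fn: FingerprintScheme) -> None:
    FINGERPRINT_SCHEMES[name] = fn


def _bond_path_string(mol: Chem.Mol, bond_path: Sequence[int]) -> str:
    """Canonical string for a linear bond path (direction-independent)."""
    bonds = [mol.GetBondWithIdx(b) for b in bond_path]
    # reconstruct the atom walk from the bond sequence
    if len(bonds) == 1:
        atoms = [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
    else:
        first = {bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()}
        second = {bonds[1].GetBeginAtomIdx(), bonds[1].GetEndAtomIdx()}
        start = (first - second).pop()
        atoms = [start]
        for b in bonds:
            a, e = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            atoms.append(e if atoms[-1] == a else a)

    def atom_token(idx: int) -> str:
        a = mol.GetAtomWithIdx(idx)
        sym = a.GetSymbol()
        return sym.lower() if a.GetIsAromatic() else sym

    bond_tokens = {
        Chem.BondType.SINGLE: "-",
        Chem.BondType.DOUBLE: "=",
        Chem.BondType.TRIPLE: "#",
        Chem.BondType.AROMATIC: ":",
    }
    parts: list[str] = [atom_token(atoms[0])]
    for b, nxt in zip(bonds, atoms[1:]):
        parts.append(bond_tokens.get(b.GetBondType(), "~"))
        parts.append(atom_token(nxt))
    fwd = "".join(parts)
    rev = "".join(reversed(parts))
    return min(fwd, rev)


def path_strings(mol: Chem.Mol, depth: int) -> set[str]:
    """All canonical linear-path strings of 1..depth bonds in a molecule."""
    out: set[str] = set()
    for n in range(1, depth + 1):
        for bond_path in Chem.FindAllPathsOfLengthN(mol, n, useBonds=True):
            out.add(_bond_path_string(mol, list(bond_path)))
    return out


def hash_path(path_string: str, nbits: int) -> int:
    """Stable bucket hash of a canonical path string (SHA-1 mod nbits)."""
    digest = hashlib.sha1(path_string.encode()).digest()
    return int.from_bytes(digest[:8], "big") % nbits


def _path_fingerprint(mol: Chem.Mol, depth: int, nbits: int) -> frozenset[int]:
    return frozenset(hash_path(s, nbits) for s in path_strings(mol, depth))


def _rdkit_fingerprint(mol: Chem.Mol, depth: int, nbits: int) -> frozenset[int]:
    bv = Chem.RDKFingerprint(mol, minPath=1, maxPath=depth, fpSize=nbits)
    return frozenset(bv.GetOnBits())


register_fingerprint_scheme("path", _path_fingerprint)
register_fingerprint_scheme("rdkit", _rdkit_fingerprint)


def compute_fingerprints(
    cs: CompoundSet,
    scheme: str = "path",
    depth: int = 4,
    nbits: int = 2048,
) -> list[Fingerprint]:
    """Topological path fingerprints for every compound in the set.

    The default ``path`` scheme enumerates all linear bond paths of
    1..``depth`` bonds, canonicalizes each to a direction-independent
    atom/bond string and hashes it into ``nbits`` buckets — an open,
    auditable analogue of depth-4 topological fingerprints.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if nbits < 1 or (nbits & (nbits - 1)) != 0:
        raise ValueError("nbits must be a power of two")
    if scheme not in FINGERPRINT_SCHEMES:
        raise ValueError(
            f"unknown fingerprint scheme {scheme!r}; "
            f"registered: {sorted(FINGERPRINT_SCHEMES)}"
        )
    fn = FINGERPRINT_SCHEMES[scheme]
    tag = f"{scheme}:{depth}:{nbits}"
    return [
        Fingerprint(compound_id=r.id, bits=fn(r.mol(), depth, nbits),
                    nbits=nbits, scheme=tag)
        for r in cs
    ]


def fingerprints_to_csv(fps: Sequence[Fingerprint], path: str | Path) -> None:
    """Serialize fingerprints as CSV with sorted on-bit index lists."""
    pd.DataFrame(
        {
            "id": [f.compound_id for f in fps],
            "scheme": [f.scheme for f in fps],
            "nbits": [f.nbits for f in fps],
            "bits": [" ".join(map(str, sorted(f.bits))) for f in fps],
        }
    ).to_csv(path, index=False)


def fingerprints_from_csv(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path, dtype={"bits": str})
    out = []
    for _, row in df.iterrows():
        bits = frozenset(int(b) for b in str(row["bits"]).split()) \
            if pd.notna(row["bits"]) and str(row["bits"]).strip() else frozenset()
        out.append(Fingerprint(row["id"], bits, int(row["nbits"]), row["scheme"]))
    return out
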