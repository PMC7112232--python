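"""Chemical I/O, descriptors, fingerprints and set-curation pruning.

Molecules are carried through the toolkit as :class:`MoleculeRecord` objects:
an identifier, a canonical SMILES, a named descriptor vector and a
fixed-length fingerprint bit array.  Descriptor computation and fingerprint
generation delegate to RDKit; the Tanimoto coefficient and the two curation
pruning rules (descriptor de-correlation at r² > 0.81 and structural
diversity pruning at TC < 0.7) are implemented here.

Lipinski counting convention used throughout: H-bond donors are the number
of N–H and O–H hydrogens (RDKit ``NHOHCount``); acceptors are the number of
N and O atoms (RDKit ``NOCount``).  Conventions differ between toolkits, so
this is stated explicitly and the four Lipinski descriptors are always named
``MolWt``, ``LogP``, ``HBD``, ``HBA``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: the four Lipinski rule-of-five descriptors; always present in a DescriptorSpec
LIPINSKI_NAMES = ("MolWt", "LogP", "HBD", "HBA")

#: open descriptor set (name -> callable on an RDKit Mol); Lipinski four first
DESCRIPTOR_FUNCTIONS: dict[str, Callable] = {
    "MolWt": Descriptors.MolWt,
    "LogP": Crippen.MolLogP,
    "HBD": Lipinski.NHOHCount,
    "HBA": Lipinski.NOCount,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumRotatableBonds": Lipinski.NumRotatableBonds,
    "RingCount": Lipinski.RingCount,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "NumAliphaticRings": rdMolDescriptors.CalcNumAliphaticRings,
    "NumSaturatedRings": rdMolDescriptors.CalcNumSaturatedRings,
    "FractionCSP3": rdMolDescriptors.CalcFractionCSP3,
    "HeavyAtomCount": Lipinski.HeavyAtomCount,
    "NumHeteroatoms": Lipinski.NumHeteroatoms,
    "MolMR": Crippen.MolMR,
    "LabuteASA": rdMolDescriptors.CalcLabuteASA,
    "BalabanJ": GraphDescriptors.BalabanJ,
    "BertzCT": GraphDescriptors.BertzCT,
    "Chi0": GraphDescriptors.Chi0,
    "Chi1": GraphDescriptors.Chi1,
    "Kappa1": GraphDescriptors.Kappa1,
    "Kappa2": GraphDescriptors.Kappa2,
    "HallKierAlpha": GraphDescriptors.HallKierAlpha,
    "MaxPartialCharge": Descriptors.MaxPartialCharge,
    "MinPartialCharge": Descriptors.MinPartialCharge,
    "NumAmideBonds": rdMolDescriptors.CalcNumAmideBonds,
    "NumSpiroAtoms": rdMolDescriptors.CalcNumSpiroAtoms,
}


class ChemError(ValueError):
    """Raised for invalid chemical input (bad SMILES, malformed library)."""


def canonical_smiles(smiles: str) -> str:
    """Return RDKit canonical SMILES; raises :class:`ChemError` if unparsable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class MoleculeRecord:
    """One molecule flowing through the screening stages.

    Parameters
    ----------
    id : str
        Identifier, unique within a library.
    smiles : str
        Canonical SMILES.
    descriptors : dict
        Descriptor name -> finite value; populated by :func:`compute_descriptors`.
    fingerprint : numpy.ndarray or None
        Boolean bit array; populated by :func:`compute_fingerprint`.
    """

    id: str
    smiles: str
    descriptors: dict[str, float] = field(default_factory=dict)
    fingerprint: np.ndarray | None = None

    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemError(f"unparsable SMILES for {mol_id!r}: {smiles!r}")
        return cls(id=mol_id, smiles=Chem.MolToSmiles(mol), _mol=mol)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
            if self._mol is None:  # pragma: no cover - smiles was canonical
                raise ChemError(f"unparsable SMILES for {self.id!r}")
        return self._mol


@dataclass(frozen=True)
class DescriptorSpec:
    """Ordered list of descriptor names; the Lipinski four are mandatory."""

    names: tuple[str, ...] = tuple(DESCRIPTOR_FUNCTIONS)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        missing = [n for n in LIPINSKI_NAMES if n not in self.names]
        if missing:
            raise ValueError(f"DescriptorSpec must include the Lipinski four; missing {missing}")
        unknown = [n for n in self.names if n not in DESCRIPTOR_FUNCTIONS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint settings.

    ``kind='path'`` is a linear-path (Daylight-like) fingerprint, the closest
    open analogue of OpenBabel FP2; ``kind='circular'`` is Morgan/ECFP.
    ``size_param`` is the maximum path length (path) or radius (circular).
    """

    kind: str = "path"
    n_bits: int = 1024
    size_param: int = 7

    def __post_init__(self) -> None:
        if self.kind not in ("path", "circular"):
            raise ValueError(f"fingerprint kind must be 'path' or 'circular', got {self.kind!r}")
        if self.n_bits < 64:
            raise ValueError("n_bits must be >= 64")


def read_smiles_library(
    path: str | Path,
    fmt: str | None = None,
    strict: bool = False,
) -> list[MoleculeRecord]:
    """Read an SMI or CSV molecule library.

    SMI format: one whitespace-separated ``SMILES [id]`` per line; missing ids
    are auto-generated as ``mol_<index>`` (1-based).  CSV format: header row
    with ``smiles`` and optional ``id`` columns.  Unparsable records are
    skipped with a logged warning, or fatal when ``strict`` is true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() in (".csv", ".tsv") else "smi"

    rows: list[tuple[int, str, str | None]] = []  # (lineno, smiles, id or None)
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            rows.append((lineno, parts[0], parts[1].strip() if len(parts) > 1 else None))
    elif fmt == "csv":
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ChemError(f"{path}: CSV library needs a 'smiles' column")
            for lineno, row in enumerate(reader, start=2):
                rows.append((lineno, row["smiles"].strip(), row.get("id") or None))
    else:
        raise ValueError(f"unknown library format {fmt!r}")

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for lineno, smiles, mol_id in rows:
        if mol_id is None:
            mol_id = f"mol_{len(records) + 1}"
        try:
            rec = MoleculeRecord.from_smiles(smiles, mol_id)
        except ChemError as exc:
            if strict:
                raise ChemError(f"{path}:{lineno}: {exc}") from exc
            logger.warning("%s:%d: skipping unparsable SMILES %r", path, lineno, smiles)
            continue
        if rec.id in seen:
            msg = f"{path}:{lineno}: duplicate id {rec.id!r}"
            if strict:
                raise ChemError(msg)
            logger.warning("%s", msg)
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise ChemError(f"{path}: zero parsable records")
    return records


def write_smiles_library(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records to an SMI file (``SMILES<TAB>id`` per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def compute_descriptors(rec: MoleculeRecord, spec: DescriptorSpec | None = None) -> MoleculeRecord:
    """Populate ``rec.descriptors`` for every name in *spec* (in place)."""
    spec = spec or DescriptorSpec()
    for name in spec.names:
        value = float(DESCRIPTOR_FUNCTIONS[name](rec.mol))
        if not np.isfinite(value):
            raise ChemError(f"descriptor {name} is non-finite for {rec.id}")
        rec.descriptors[name] = value
    return rec


def descriptor_table(
    records: Sequence[MoleculeRecord],
    spec: DescriptorSpec | None = None,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Descriptor DataFrame indexed by molecule id (optionally with a ``label`` column)."""
    spec = spec or DescriptorSpec()
    for rec in records:
        if not all(n in rec.descriptors for n in spec.names):
            compute_descriptors(rec, spec)
    df = pd.DataFrame(
        [[rec.descriptors[n] for n in spec.names] for rec in records],
        index=pd.Index([rec.id for rec in records], name="id"),
        columns=list(spec.names),
    )
    if labels is not None:
        df["label"] = list(labels)
    return df


def compute_fingerprint(rec: MoleculeRecord, cfg: FingerprintConfig | None = None) -> np.ndarray:
    """Compute the fingerprint bit array for *rec* (cached on the record)."""
    cfg = cfg or FingerprintConfig()
    if cfg.kind == "path":
        bv = Chem.RDKFingerprint(rec.mol, maxPath=cfg.size_param, fpSize=cfg.n_bits)
    else:
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.size_param, fpSize=cfg.n_bits)
        bv = gen.GetFingerprint(rec.mol)
    arr = np.zeros(cfg.n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    rec.fingerprint = arr
    return arr


def ensure_fingerprints(
    records: Sequence[MoleculeRecord], cfg: FingerprintConfig | None = None
) -> None:
    for rec in records:
        if rec.fingerprint is None:
            compute_fingerprint(rec, cfg)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| between two equal-length bit arrays.

    Two empty bitsets have an undefined ratio; by convention 0.0 is returned
    (with a warning), so that degenerate molecules never count as similar.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bitset length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        logger.warning("tanimoto of two empty bitsets; returning 0.0 by convention")
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(fps_a: Sequence[np.ndarray], fps_b: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise Tanimoto matrix between two fingerprint lists (vectorized)."""
    A = np.asarray(fps_a, dtype=bool)
    B = np.asarray(fps_b, dtype=bool)
    inter = A.astype(np.int32) @ B.T.astype(np.int32)
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return tc


def prune_correlated_descriptors(
    table: pd.DataFrame,
    r2_max: float = 0.81,
) -> tuple[list[str], list[dict]]:
    """Remove descriptors until no pair has squared Pearson correlation > ``r2_max``.

    At each step, among all currently violating pairs, the descriptor with
    the larger sum of r² against all other remaining descriptors is removed
    (ties broken by removing the lexicographically later name).  Constant
    columns are removed first, since their correlation is undefined.

    Returns the surviving descriptor names (input order) and a removal log.
    """
    cols = [c for c in table.columns if c != "label"]
    if len(cols) < 2 or len(table) < 3:
        raise ValueError("need >=2 descriptors and >=3 molecules")
    log: list[dict] = []
    values = table[cols].astype(float)

    constant = [c for c in cols if values[c].nunique() <= 1]
    for c in constant:
        log.append({"removed": c, "reason": "constant column"})
    kept = [c for c in cols if c not in constant]

    r2 = values[kept].corr() ** 2
    np.fill_diagonal(r2.values, 0.0)
    while kept:
        sub = r2.loc[kept, kept]
        violating = sub.max() > r2_max
        if not violating.any():
            break
        offenders = sorted(violating[violating].index)
        sums = sub.loc[offenders].sum(axis=1)
        worst = max(offenders, key=lambda c: (sums[c], c))
        partners = sorted(sub.columns[sub.loc[worst] > r2_max])
        log.append(
            {
                "removed": worst,
                "reason": f"r2 > {r2_max} with {partners}",
                "r2_sum": float(sums[worst]),
            }
        )
        kept.remove(worst)
    return kept, log


def diversity_prune(
    mols: Sequence[MoleculeRecord],
    tc_max: float = 0.7,
    cfg: FingerprintConfig | None = None,
) -> tuple[list[MoleculeRecord], list[dict]]:
    """Prune a set until every surviving pair has Tanimoto < ``tc_max``.

    Of each violating pair, the molecule with the larger sum of TCs against
    all other remaining molecules is removed; equal sums remove the
    lexicographically later id.  Deterministic for a fixed input order.
    """
    if len(mols) <= 1:
        return list(mols), []
    ensure_fingerprints(mols, cfg)
    fps = [m.fingerprint for m in mols]
    tc = tanimoto_matrix(fps, fps)
    np.fill_diagonal(tc, 0.0)
    ids = [m.id for m in mols]
    alive = list(range(len(mols)))
    log: list[dict] = []
    while True:
        sub = tc[np.ix_(alive, alive)]
        if not (sub >= tc_max).any():
            break
        sums = sub.sum(axis=1)
        offenders = [k for k in range(len(alive)) if sub[k].max() >= tc_max]
        worst_local = max(offenders, key=lambda k: (sums[k], ids[alive[k]]))
        worst = alive[worst_local]
        log.append({"removed": ids[worst], "tc_sum": float(sums[worst_local])})
        alive.remove(worst)
    return [mols[i] for i in alive], log
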