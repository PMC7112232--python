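"""Derivation of P5–P2 fragments by cleaving off proline-like P1 rings.

Full inhibitors of proline-cleaving proteases typically carry an acylated
pyrrolidine or piperidine that occupies the S1 subpocket.  To model the
region N-terminal of P2 (subpockets S2–S5), that ring — and everything on
its side of the acyl bond — is removed, retaining the carbonyl-side portion.
Fragments are deduplicated by canonical SMILES into a :class:`FragmentSet`
with provenance back to the parent inhibitors, and cross-set Tanimoto
matrices compare fragment collections.

The cleavage site is defined by substructure patterns (SMARTS) matching an
sp2 carbonyl carbon bonded to the ring nitrogen; the cleaved bond is that
amide C–N bond.  The open valence on the carbonyl carbon is capped with
hydroxyl by default (yielding a carboxylic acid, which preserves the
H-bonding character of the original amide) or with hydrogen on request.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .chemlib import (
    ChemError,
    FingerprintConfig,
    MoleculeRecord,
    ensure_fingerprints,
    read_smiles_library,
    tanimoto_matrix,
    write_smiles_library,
)

logger = logging.getLogger(__name__)

#: acyl-pyrrolidine and acyl-piperidine; atom 0 = carbonyl C, atom 2 = ring N
DEFAULT_RING_PATTERNS = (
    "[CX3](=[OX1])[NX3]1[CX4][CX4][CX4][CX4]1",
    "[CX3](=[OX1])[NX3]1[CX4][CX4][CX4][CX4][CX4]1",
)


@dataclass(frozen=True)
class CleavageRule:
    """How to find and cut the P1-parallel ring.

    ``ring_patterns`` are SMARTS whose first atom is the acyl carbonyl carbon
    and whose third atom is the ring nitrogen; the C–N bond between them is
    cleaved and everything on the ring side (including ring substituents) is
    discarded.  ``capping`` is ``'hydroxyl'`` (carboxylic acid terminus,
    default) or ``'hydrogen'`` (aldehyde terminus).
    """

    ring_patterns: tuple[str, ...] = DEFAULT_RING_PATTERNS
    capping: str = "hydroxyl"

    def __post_init__(self) -> None:
        if self.capping not in ("hydroxyl", "hydrogen"):
            raise ValueError("capping must be 'hydroxyl' or 'hydrogen'")
        for p in self.ring_patterns:
            if Chem.MolFromSmarts(p) is None:
                raise ValueError(f"unparsable SMARTS pattern: {p!r}")

    @property
    def queries(self) -> list[Chem.Mol]:
        return [Chem.MolFromSmarts(p) for p in self.ring_patterns]


@dataclass
class FragmentSet:
    """Deduplicated fragments with provenance to parent inhibitors."""

    fragments: list[MoleculeRecord] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def save(self, smi_path: str | Path, provenance_path: str | Path | None = None) -> None:
        smi_path = Path(smi_path)
        write_smiles_library(self.fragments, smi_path)
        prov = Path(provenance_path) if provenance_path else smi_path.with_suffix(".provenance.json")
        prov.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def load(cls, smi_path: str | Path, provenance_path: str | Path | None = None) -> "FragmentSet":
        smi_path = Path(smi_path)
        prov = Path(provenance_path) if provenance_path else smi_path.with_suffix(".provenance.json")
        provenance = json.loads(prov.read_text()) if prov.exists() else {}
        return cls(fragments=read_smiles_library(smi_path), provenance=provenance)


def _matches_any(mol: Chem.Mol, rule: CleavageRule) -> bool:
    return any(mol.HasSubstructMatch(q) for q in rule.queries)


def _cleave_once(mol: Chem.Mol, carbonyl_idx: int, ring_n_idx: int, capping: str) -> Chem.Mol:
    """Break the acyl C–N bond and return the sanitized carbonyl-side fragment."""
    rw = Chem.RWMol(mol)
    rw.RemoveBond(carbonyl_idx, ring_n_idx)
    if capping == "hydroxyl":
        o_idx = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(carbonyl_idx, o_idx, Chem.BondType.SINGLE)
    # locate the fragment containing the carbonyl carbon via atom maps
    for atom in rw.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    frags = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False)
    keep = None
    for frag in frags:
        if any(a.GetAtomMapNum() == carbonyl_idx + 1 for a in frag.GetAtoms()):
            keep = frag
            break
    assert keep is not None
    for a in keep.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.SanitizeMol(keep)
    if any(a.GetNumRadicalElectrons() for a in keep.GetAtoms()):  # pragma: no cover
        raise ChemError("cleavage produced a radical")
    return keep


def cleave_p1_fragment(rec: MoleculeRecord, rule: CleavageRule | None = None) -> list[MoleculeRecord]:
    """Cleave every proline-like acyl-ring site of *rec*.

    Returns one fragment per distinct cleavage site, each guaranteed free of
    any ring pattern (sites remaining after a first cut are cleaved
    recursively).  A molecule with no cleavage site yields an empty list and
    a logged notice, not an exception.
    """
    rule = rule or CleavageRule()
    sites: list[tuple[int, int]] = []
    for query in rule.queries:
        for match in rec.mol.GetSubstructMatches(query):
            site = (match[0], match[2])  # (carbonyl C, ring N)
            if site not in sites:
                sites.append(site)
    if not sites:
        logger.info("no cleavage site in %s", rec.id)
        return []
    out: list[MoleculeRecord] = []
    for k, (c_idx, n_idx) in enumerate(sites, start=1):
        frag = _cleave_once(rec.mol, c_idx, n_idx, rule.capping)
        frag_rec = MoleculeRecord.from_smiles(Chem.MolToSmiles(frag), f"{rec.id}_frag{k}")
        # a retained portion may still carry another proline-like site
        while _matches_any(frag_rec.mol, rule):
            inner = cleave_p1_fragment(frag_rec, rule)
            if not inner:  # pragma: no cover - matched but uncleavable
                break
            frag_rec = MoleculeRecord(id=frag_rec.id, smiles=inner[0].smiles)
        out.append(frag_rec)
    return out


def build_fragment_set(
    inhibitors: Sequence[MoleculeRecord], rule: CleavageRule | None = None
) -> FragmentSet:
    """Cleave all inhibitors and deduplicate fragments by canonical SMILES."""
    if not inhibitors:
        raise ValueError("need at least one inhibitor")
    rule = rule or CleavageRule()
    by_smiles: dict[str, list[str]] = {}
    for rec in inhibitors:
        for frag in cleave_p1_fragment(rec, rule):
            by_smiles.setdefault(frag.smiles, [])
            if rec.id not in by_smiles[frag.smiles]:
                by_smiles[frag.smiles].append(rec.id)
    fset = FragmentSet()
    if not by_smiles:
        logger.warning("no inhibitor had a cleavage site; fragment set is empty")
        return fset
    for k, (smiles, parents) in enumerate(sorted(by_smiles.items()), start=1):
        frag_id = f"frag_{k}"
        fset.fragments.append(MoleculeRecord.from_smiles(smiles, frag_id))
        fset.provenance[frag_id] = parents
    return fset


def cross_set_similarity(
    set_a: FragmentSet,
    set_b: FragmentSet,
    cfg: FingerprintConfig | None = None,
) -> pd.DataFrame:
    """Tanimoto matrix between two fragment sets, with a per-row ``max_tc`` column.

    Rows are set A fragments, columns set B fragments; identical members
    across the sets show up as entries of exactly 1.0.
    """
    if not set_a.fragments or not set_b.fragments:
        raise ValueError("both fragment sets must be non-empty")
    ensure_fingerprints(set_a.fragments, cfg)
    ensure_fingerprints(set_b.fragments, cfg)
    tc = tanimoto_matrix(
        [f.fingerprint for f in set_a.fragments],
        [f.fingerprint for f in set_b.fragments],
    )
    df = pd.DataFrame(
        tc,
        index=pd.Index([f.id for f in set_a.fragments], name="set_a"),
        columns=[f.id for f in set_b.fragments],
    )
    df["max_tc"] = df.max(axis=1)
    return df
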