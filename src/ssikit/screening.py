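"""Candidate-generation funnel stages.

Order of the funnel (each stage's output is a subset of its input):

1. similarity screen — keep library molecules with Tanimoto ≥ 0.6 to at
   least one fragment of the reference fragment set;
2. applicability domain — keep molecules whose four Lipinski descriptors
   all lie within mean ± 2σ of the active set;
3. MBI scoring by an ISE model (see :mod:`ssikit.ise`);
4. solubility consensus gate — mean predicted cLogS > −3.5 with standard
   deviation < 1.5 across ≥ 2 estimators;
5. candidate tiering by MBI thresholds.

All interval checks use closed boundaries (a value exactly on a bound
passes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chemlib import (
    LIPINSKI_NAMES,
    FingerprintConfig,
    MoleculeRecord,
    ensure_fingerprints,
    tanimoto_matrix,
)
from .fragments import FragmentSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# similarity screen
# ---------------------------------------------------------------------------


def similarity_screen(
    library: Sequence[MoleculeRecord],
    fragments: FragmentSet,
    tc_min: float = 0.6,
    cfg: FingerprintConfig | None = None,
) -> pd.DataFrame:
    """Tanimoto screen of a library against a fragment set.

    Returns a DataFrame indexed by molecule id with columns ``tc_best``,
    ``frag_best`` (ties resolved to the lowest fragment id) and ``hit``
    (``tc_best >= tc_min``).
    """
    if not fragments.fragments:
        raise ValueError("fragment set is empty")
    if not library:
        return pd.DataFrame(columns=["tc_best", "frag_best", "hit"])
    ensure_fingerprints(library, cfg)
    ensure_fingerprints(fragments.fragments, cfg)
    frag_ids = np.array([f.id for f in fragments.fragments])
    order = np.argsort(frag_ids, kind="stable")  # lowest id wins argmax ties
    tc = tanimoto_matrix([m.fingerprint for m in library],
                         [fragments.fragments[i].fingerprint for i in order])
    best_col = np.argmax(tc, axis=1)  # first (lowest-id) maximum
    best_tc = tc[np.arange(len(library)), best_col]
    return pd.DataFrame(
        {
            "tc_best": best_tc,
            "frag_best": frag_ids[order][best_col],
            "hit": best_tc >= tc_min,
        },
        index=pd.Index([m.id for m in library], name="id"),
    )


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApplicabilityDomain:
    """Per-descriptor mean ± 2σ ranges fitted on the active set."""

    ranges: Mapping[str, tuple[float, float]]
    n_defining: int
    degenerate: tuple[str, ...] = ()

    def contains(self, descriptors: Mapping[str, float]) -> list[str]:
        """Names of violated descriptors (empty list = inside the domain)."""
        violated = []
        for name, (lo, hi) in self.ranges.items():
            v = descriptors[name]
            if not (lo <= v <= hi):
                violated.append(name)
        return violated


def fit_applicability_domain(
    actives: Sequence[MoleculeRecord] | pd.DataFrame,
    names: Sequence[str] = LIPINSKI_NAMES,
    n_sigma: float = 2.0,
) -> ApplicabilityDomain:
    """Fit mean ± ``n_sigma``·σ ranges (sample σ, ddof=1) per descriptor.

    A zero-variance descriptor yields a degenerate range at its value,
    flagged in ``degenerate`` and treated as an equality constraint.
    """
    if isinstance(actives, pd.DataFrame):
        table = actives
    else:
        table = pd.DataFrame(
            {name: [m.descriptors[name] for m in actives] for name in names}
        )
    if len(table) < 3:
        raise ValueError("need >= 3 actives to fit an applicability domain")
    ranges: dict[str, tuple[float, float]] = {}
    degenerate: list[str] = []
    for name in names:
        v = table[name].to_numpy(dtype=float)
        mu = v.mean()
        sd = v.std(ddof=1)
        if sd == 0:
            degenerate.append(name)
            logger.warning("applicability domain: %s has zero variance; equality constraint", name)
        ranges[name] = (mu - n_sigma * sd, mu + n_sigma * sd)
    return ApplicabilityDomain(ranges=ranges, n_defining=len(table), degenerate=tuple(degenerate))


def apply_applicability_domain(
    library: Sequence[MoleculeRecord],
    domain: ApplicabilityDomain,
) -> tuple[list[MoleculeRecord], dict[str, list[str]]]:
    """Keep molecules inside the closed domain on every descriptor.

    Returns the kept subset (input order) and a map of rejected id → list of
    violated descriptor names.
    """
    kept: list[MoleculeRecord] = []
    rejections: dict[str, list[str]] = {}
    for rec in library:
        violated = domain.contains(rec.descriptors)
        if violated:
            rejections[rec.id] = violated
        else:
            kept.append(rec)
    return kept, rejections


# ---------------------------------------------------------------------------
# solubility consensus gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolubilityConsensus:
    mol_id: str
    predictions: tuple[float, ...]
    mean: float
    std: float
    passed: bool
    insufficient: bool = False


def esol_logs(rec: MoleculeRecord) -> float:
    """Built-in logS estimator: the ESOL linear model on four 2D descriptors.

    logS = 0.16 − 0.63·cLogP − 0.0062·MW + 0.066·RB − 0.74·AP, with AP the
    aromatic proportion (aromatic atoms / heavy atoms).  A fast, documented
    heuristic — accurate to roughly ±1 log unit on drug-like molecules.
    """
    mol = rec.mol
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return (
        0.16
        - 0.63 * Crippen.MolLogP(mol)
        - 0.0062 * Descriptors.MolWt(mol)
        + 0.066 * Lipinski.NumRotatableBonds(mol)
        - 0.74 * ap
    )


def logp_rule_logs(rec: MoleculeRecord) -> float:
    """Crude logS rule of thumb: logS ≈ 0.5 − logP.

    A deliberately different (one-descriptor) estimator so a consensus of
    built-ins has non-zero spread; replace with external predictors when
    available.
    """
    return 0.5 - Crippen.MolLogP(rec.mol)


def predict_solubility(
    records: Sequence[MoleculeRecord],
    estimators: Sequence[Callable[[MoleculeRecord], float]],
) -> dict[str, list[float]]:
    """Apply each pluggable cLogS estimator to each molecule."""
    return {rec.id: [float(est(rec)) for est in estimators] for rec in records}


def solubility_gate(
    predictions: Mapping[str, Sequence[float]],
    mean_min: float = -3.5,
    std_max: float = 1.5,
) -> list[SolubilityConsensus]:
    """Consensus gate: pass iff mean cLogS > ``mean_min`` and sample std < ``std_max``.

    Molecules with fewer than two predictions are marked insufficient and do
    not pass.
    """
    out: list[SolubilityConsensus] = []
    for mol_id, preds in predictions.items():
        preds = tuple(float(p) for p in preds)
        if len(preds) < 2:
            out.append(
                SolubilityConsensus(mol_id, preds, float("nan"), float("nan"), False, True)
            )
            continue
        mean = float(np.mean(preds))
        std = float(np.std(preds, ddof=1))
        out.append(SolubilityConsensus(mol_id, preds, mean, std, mean > mean_min and std < std_max))
    return out


# ---------------------------------------------------------------------------
# candidate tiering
# ---------------------------------------------------------------------------

TIERS = ("top_ise", "mid_ise", "low_mbi_similar", "none")


@dataclass(frozen=True)
class TierThresholds:
    """MBI cutoffs for the candidate tiers.

    ``top_ise``: MBI > top; ``mid_ise``: mid < MBI ≤ top; ``low_mbi_similar``:
    MBI < low AND the molecule is a similarity hit (structural similarity
    alone, with a very poor model score — picked to probe whether similarity
    is sufficient for activity).
    """

    top: float = 0.85
    mid: float = 0.2
    low: float = -0.97


def tier_candidates(
    scores: pd.DataFrame,
    thresholds: TierThresholds | None = None,
    similar_col: str = "hit",
) -> pd.Series:
    """Assign each scored molecule to a candidate tier.

    *scores* must have an ``mbi`` column; a boolean *similar_col* column is
    optional (assumed False when absent).  Returns a Series of tier names.
    """
    th = thresholds or TierThresholds()
    mbi = scores["mbi"].to_numpy(dtype=float)
    similar = (
        scores[similar_col].to_numpy(dtype=bool)
        if similar_col in scores.columns
        else np.zeros(len(scores), dtype=bool)
    )
    tier = np.full(len(scores), "none", dtype=object)
    tier[(mbi < th.low) & similar] = "low_mbi_similar"
    tier[(mbi > th.mid) & (mbi <= th.top)] = "mid_ise"
    tier[mbi > th.top] = "top_ise"
    return pd.Series(tier, index=scores.index, name="tier")
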