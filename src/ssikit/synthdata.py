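"""Deterministic generators for every input class the pipeline consumes.

Three generators, all pure functions of (spec, seed):

* planted-signal descriptor tables — actives occupy narrow sub-ranges of a
  few "signal" descriptors while inactives are diffuse, at a class imbalance
  near 1:200 (the regime virtual-screening learning sets live in);
* toy SMILES libraries — acyl-pyrrolidine/piperidine inhibitor-like
  scaffolds (cleavable by the default fragment rule) and scaffold-diverse
  decoys;
* Michaelis–Menten initial-rate data under competitive / noncompetitive /
  uncompetitive inhibition with multiplicative Gaussian noise (constant CV,
  the usual assumption for initial-rate assays).

The planted ground truth is returned alongside each dataset so recovery
tests can assert against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemlib import MoleculeRecord
from .kinetics import KineticsMeasurement

# ---------------------------------------------------------------------------
# planted descriptor tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDescriptorSpec:
    """Ground-truth layout of a synthetic learning set.

    Defaults mirror a realistic screening learning set: 30 actives diluted
    in 6000 inactives (≈1:200), four signal descriptors with planted active
    sub-ranges of width 0.2 on [0, 1], 26 uninformative descriptors, and a
    5% chance for an active to "leak": an off-mechanism outlier whose signal
    descriptors are drawn uniform like an inactive's.
    """

    n_actives: int = 30
    n_inactives: int = 6000
    n_signal_descriptors: int = 4
    n_noise_descriptors: int = 26
    signal_width: float = 0.2
    leak_probability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.signal_width < 1):
            raise ValueError("signal_width must be in (0, 1)")
        if not (0 <= self.leak_probability < 0.5):
            raise ValueError("leak_probability must be in [0, 0.5)")
        if min(self.n_actives, self.n_inactives, self.n_signal_descriptors) < 1:
            raise ValueError("counts must be positive")


def gen_descriptor_dataset(spec: PlantedDescriptorSpec) -> tuple[pd.DataFrame, dict]:
    """Labeled descriptor table plus the planted ground truth.

    Returns ``(table, truth)``: the table has columns ``sig_1..sig_k``,
    ``noise_1..noise_m`` and ``label`` (1 = active), indexed by molecule id;
    ``truth`` records the signal descriptor names and their planted ranges.
    """
    rng = np.random.default_rng(spec.seed)
    sig_names = [f"sig_{i + 1}" for i in range(spec.n_signal_descriptors)]
    noise_names = [f"noise_{i + 1}" for i in range(spec.n_noise_descriptors)]
    # planted range positions drawn first so the truth is fixed by the seed
    starts = rng.uniform(0, 1 - spec.signal_width, size=spec.n_signal_descriptors)
    ranges = {name: (float(s), float(s + spec.signal_width)) for name, s in zip(sig_names, starts)}

    n_total = spec.n_actives + spec.n_inactives
    data: dict[str, np.ndarray] = {}
    # leaks are whole molecules: a leaked active is drawn uniform on every
    # signal descriptor (an "off-mechanism" active), not perturbed per-descriptor
    leaks = rng.random(spec.n_actives) < spec.leak_probability
    for name in sig_names:
        lo, hi = ranges[name]
        active_vals = rng.uniform(lo, hi, size=spec.n_actives)
        active_vals[leaks] = rng.uniform(0, 1, size=int(leaks.sum()))
        inactive_vals = rng.uniform(0, 1, size=spec.n_inactives)
        data[name] = np.concatenate([active_vals, inactive_vals])
    for name in noise_names:
        data[name] = rng.uniform(0, 1, size=n_total)
    labels = np.concatenate(
        [np.ones(spec.n_actives, dtype=int), np.zeros(spec.n_inactives, dtype=int)]
    )
    ids = [f"act_{i + 1}" for i in range(spec.n_actives)] + [
        f"inact_{i + 1}" for i in range(spec.n_inactives)
    ]
    table = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    table["label"] = labels
    truth = {"signal_descriptors": sig_names, "ranges": ranges, "seed": spec.seed}
    return table, truth


# ---------------------------------------------------------------------------
# toy SMILES libraries
# ---------------------------------------------------------------------------

# acyl groups R-C(=O)- attached to the ring nitrogen; the retained P5-P2 side
_ACYL_GROUPS = (
    "c1ccccc1",  # benzoyl
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccc(C)cc1",
    "c1ccc(OC)cc1",
    "Cc1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",  # naphthoyl
    "Cc1ccco1",
    "CC(C)C",
    "CCCC",
    "CC(C)(C)C",
    "Cc1ccccc1O",
    "CCc1ccccc1",
    "c1ccc(CC#N)cc1",
    "OCc1ccccc1",
)

#: proline-like ring cores (pyrrolidine, piperidine) acylated at nitrogen
_RING_CORES = ("N1CCCC1", "N1CCCCC1")

#: scaffold-diverse decoys with no acyl-pyrrolidine/piperidine motif
_DECOY_SCAFFOLDS = (
    "c1ccc(Oc2ccccc2)cc1",
    "CCOC(=O)c1ccccc1",
    "CC(C)Nc1ncccn1",
    "COc1ccc(S(N)(=O)=O)cc1",
    "CCN(CC)CCOc1ccccc1",
    "Cc1nc2ccccc2s1",
    "O=C(O)c1ccc(O)cc1",
    "c1ccc(-c2ccccc2)cc1",
    "CC(O)c1ccc(C)cc1",
    "COC(=O)CCc1ccccc1",
    "Nc1ccc(C(=O)O)cc1",
    "CCCCCCCCO",
    "CC(C)(C)c1ccc(O)cc1",
    "O=S(=O)(c1ccccc1)N1CCOCC1",
    "Clc1ccc(CN2CCOCC2)cc1",
    "CC1=CC(=O)CC(C)(C)C1",
    "c1ccc2[nH]ccc2c1",
    "COc1cccc(C=O)c1",
    "CN(C)c1ccccn1",
    "OCC(O)COc1ccccc1",
)


# building blocks for combinatorial decoys: R1 + linker + R2 concatenation
_DECOY_R1 = ("c1ccccc1", "Cc1ccccc1", "COc1ccccc1", "Fc1ccccc1", "CC(C)", "CCC", "c1ccncc1", "Clc1ccccc1")
_DECOY_LINKERS = ("C(=O)O", "OC", "S(=O)(=O)N")
_DECOY_R2 = ("CC", "CCC", "CCO", "Cc1ccccc1", "CCN(C)C", "CC(C)O")


def _inhibitor_like_variants() -> list[str]:
    return [f"O=C({acyl}){core}" for core in _RING_CORES for acyl in _ACYL_GROUPS]


def _random_like_variants() -> list[str]:
    combinatorial = [r1 + link + r2 for r1 in _DECOY_R1 for link in _DECOY_LINKERS for r2 in _DECOY_R2]
    return list(_DECOY_SCAFFOLDS) + combinatorial


def gen_smiles_fixture(kind: str, n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Deterministic toy SMILES library.

    ``kind='inhibitor_like'`` draws from enumerated acyl-pyrrolidine and
    acyl-piperidine variants (all cleavable by the default cleavage rule);
    ``kind='random_like'`` draws scaffold-diverse decoys with no
    proline-like acyl ring.  Raises if *n* exceeds the enumerable variants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "inhibitor_like":
        variants = _inhibitor_like_variants()
    elif kind == "random_like":
        variants = _random_like_variants()
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if n > len(variants):
        raise ValueError(f"n={n} exceeds the {len(variants)} enumerable {kind} variants")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(variants), size=n, replace=False)
    prefix = "inh" if kind == "inhibitor_like" else "dec"
    return [
        MoleculeRecord.from_smiles(variants[int(i)], f"{prefix}_{k + 1}")
        for k, i in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# kinetics simulation
# ---------------------------------------------------------------------------

MECHANISMS = ("none", "competitive", "noncompetitive", "uncompetitive")


@dataclass(frozen=True)
class KineticsSimSpec:
    """Rate-law simulation settings (concentrations in µM, rates in µM/min)."""

    km: float = 5.0
    vmax: float = 2.0
    mechanism: str = "none"
    ki: float = 10.0
    substrate_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    inhibitor_grid: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0  # relative (multiplicative) noise
    seed: int = 0
    substrate: str = "S"
    inhibitor: str = "I"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if min(self.km, self.vmax, self.ki) <= 0:
            raise ValueError("km, vmax and ki must be positive")
        if not self.substrate_grid or not len(self.inhibitor_grid):
            raise ValueError("grids must be non-empty")


def rate_law(spec: KineticsSimSpec, s: float, i: float) -> float:
    """Closed-form initial rate for the spec's mechanism at [S] = s, [I] = i."""
    a = 1.0 + i / spec.ki
    if spec.mechanism == "none" or i == 0:
        return spec.vmax * s / (spec.km + s)
    if spec.mechanism == "competitive":
        return spec.vmax * s / (spec.km * a + s)
    if spec.mechanism == "noncompetitive":
        return (spec.vmax / a) * s / (spec.km + s)
    # uncompetitive
    return spec.vmax * s / (spec.km + s * a)


def gen_kinetics_data(spec: KineticsSimSpec) -> list[KineticsMeasurement]:
    """Initial-rate observations on the full substrate × inhibitor grid.

    Rates are the mechanism's closed-form law times ``1 + noise`` with noise
    ~ N(0, noise_sd), clipped at zero; deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[KineticsMeasurement] = []
    for i in spec.inhibitor_grid:
        for s in spec.substrate_grid:
            v = rate_law(spec, s, i)
            if spec.noise_sd > 0:
                v *= 1.0 + rng.normal(0.0, spec.noise_sd)
            out.append(
                KineticsMeasurement(
                    substrate=spec.substrate,
                    inhibitor=spec.inhibitor,
                    substrate_conc=float(s),
                    inhibitor_conc=float(i),
                    rate=max(0.0, float(v)),
                )
            )
    return out
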