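"""Descriptor-based product prioritization.

Products are profiled with a pluggable descriptor backend (the default
computes deterministic physicochemical descriptors with RDKit), ranked by
empirical percentile against a reference compound set, and flagged when they
fall in the adverse-direction extreme tail (top 1st percentile by default)
for at least one descriptor. The adverse direction (higher-worse vs
lower-worse) is explicit per-descriptor configuration, never inferred.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_PLUGINS",
    "DEFAULT_DIRECTIONS",
    "register_plugin",
    "compute_descriptors",
    "empirical_percentile",
    "flag_extremes",
]


def _physchem(mol: Chem.Mol) -> dict[str, float]:
    return {
        "mol_weight": Descriptors.MolWt(mol),
        "clogp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hbd": float(Lipinski.NumHDonors(mol)),
        "hba": float(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
        "aromatic_rings": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "qed": QED.qed(mol),
    }


#: Registered descriptor backends; each maps a sanitized Mol to name→value.
DESCRIPTOR_PLUGINS: dict[str, Callable[[Chem.Mol], dict[str, float]]] = {
    "physchem": _physchem,
}

#: Adverse direction per default descriptor: "higher" means large values are
#: adverse (e.g. lipophilicity), "lower" means small values are adverse
#: (e.g. drug-likeness QED).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "mol_weight": "higher",
    "clogp": "higher",
    "tpsa": "higher",
    "hbd": "higher",
    "hba": "higher",
    "rotatable_bonds": "higher",
    "aromatic_rings": "higher",
    "fraction_csp3": "lower",
    "qed": "lower",
}


def register_plugin(
    name: str, fn: Callable[[Chem.Mol], dict[str, float]]
) -> None:
    """Register an alternative descriptor backend (e.g. a trained-model
    ADME/Tox predictor) under ``name``."""
    DESCRIPTOR_PLUGINS[name] = fn


def compute_descriptors(
    smiles: Sequence[str], plugin: str = "physchem"
) -> pd.DataFrame:
    """Descriptor profiles for a SMILES list (index = input position).

    Unparsable SMILES raise; per-molecule descriptor failures leave that
    molecule's row as missing values with a warning.
    """
    if plugin not in DESCRIPTOR_PLUGINS:
        raise KeyError(
            f"unknown descriptor plugin {plugin!r}; "
            f"registered: {sorted(DESCRIPTOR_PLUGINS)}"
        )
    fn = DESCRIPTOR_PLUGINS[plugin]
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smi!r}")
        try:
            rows.append(fn(mol))
        except Exception as exc:
            logger.warning("descriptor failure for %s: %s", smi, exc)
            rows.append({})
    return pd.DataFrame(rows)


def empirical_percentile(reference: np.ndarray, value: float) -> float:
    """Empirical percentile of ``value`` in ``reference`` with midpoint tie
    handling: 100 * (#less + 0.5 * #equal) / n."""
    reference = np.asarray(reference, dtype=float)
    reference = reference[~np.isnan(reference)]
    n = reference.size
    if n == 0:
        return math.nan
    less = float(np.count_nonzero(reference < value))
    equal = float(np.count_nonzero(reference == value))
    return 100.0 * (less + 0.5 * equal) / n


def flag_extremes(
    profiles: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = 1.0,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flag products in the adverse-direction top ``threshold`` percent.

    A product is flagged when, for at least one configured descriptor, its
    empirical percentile against the reference lies beyond
    ``100 - threshold`` (higher-worse) or below ``threshold`` (lower-worse).
    Percentiles are computed against the reference only; products never
    contaminate the reference distribution. Descriptors present in the
    products but absent from the reference are skipped with a warning.

    Returns a copy of ``profiles`` with per-descriptor ``pct_*`` columns, a
    boolean ``flagged`` column, and ``flag_reasons`` listing the triggering
    descriptors.
    """
    if reference.empty:
        raise ValueError("reference set is empty")
    if not 0 < threshold < 100:
        raise ValueError("threshold percentile must be in (0, 100)")
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    out = profiles.copy()
    reasons: list[list[str]] = [[] for _ in range(len(profiles))]
    for col, direction in directions.items():
        if col not in profiles.columns:
            continue
        if col not in reference.columns:
            logger.warning("descriptor %r absent from reference: skipped", col)
            continue
        if direction not in ("higher", "lower"):
            raise ValueError(f"descriptor {col!r}: bad direction {direction!r}")
        ref = reference[col].to_numpy(dtype=float)
        pcts = np.array(
            [
                empirical_percentile(ref, v) if not pd.isna(v) else math.nan
                for v in profiles[col]
            ]
        )
        out[f"pct_{col}"] = pcts
        if direction == "higher":
            hit = pcts >= 100.0 - threshold
        else:
            hit = pcts <= threshold
        hit = np.where(np.isnan(pcts), False, hit)
        for i in np.flatnonzero(hit):
            reasons[i].append(col)
    out["flagged"] = [bool(r) for r in reasons]
    out["flag_reasons"] = ["|".join(r) for r in reasons]
    return out
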