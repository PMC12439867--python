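"""Scikit-learn style estimators wrapping the pipeline stages.

The fit/transform-shaped stages are exposed as estimators so they compose
with sklearn pipelines and model selection:

* :class:`TransformationEnumerator` — fit on reaction records (builds the
  template/substructure database), transform query SMILES into a product
  table.
* :class:`ReactionAnnotator` — stateless transformer from mapped reaction
  SMILES to per-reaction annotations.
* :class:`DescriptorCalculator` — SMILES → descriptor DataFrame.
* :class:`ExtremeFlagger` — fit on a reference descriptor set, transform
  product descriptors into percentile flags.

The module-level functions in :mod:`ista.templates`, :mod:`ista.engine` and
:mod:`ista.prioritize` are the underlying implementations.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import annotation, engine, prioritize, templates
from .center import SanitizationError, sanitize_mapped_reaction
from .io import ReactionRecord

__all__ = [
    "TransformationEnumerator",
    "ReactionAnnotator",
    "DescriptorCalculator",
    "ExtremeFlagger",
]


class TransformationEnumerator(BaseEstimator, TransformerMixin):
    """Learn transformation templates from reactions; enumerate products.

    Parameters
    ----------
    fg_library_path : str or None
        Path to a functional-group TSV; None uses the packaged two-tier
        library (detection n=107, expansion n=30).
    multi_reactant_policy : {"fill", "single_only"}
        How multi-reactant templates treat a single query: fill the other
        roles with the source reaction's co-reactants, or skip the template.
    dedup_scope : {"per_query", "global"}
        Whether product deduplication is per query or across the run.
    exclude_parent : bool
        Drop products structure-identical to their query.
    apply_filter : bool
        Run CID redundancy/missing-value filtering before extraction.
    use_screen : bool
        Screen by reactive substructure before applying templates (False
        applies every template exhaustively; the oracle path).

    Attributes
    ----------
    templates_ : DataFrame of extracted templates.
    substructures_ : DataFrame of reactive-site substructures.
    skip_report_ : dict of per-stage skip counts.
    """

    def __init__(
        self,
        fg_library_path: str | None = None,
        multi_reactant_policy: str = "fill",
        dedup_scope: str = "per_query",
        exclude_parent: bool = True,
        apply_filter: bool = True,
        use_screen: bool = True,
    ):
        self.fg_library_path = fg_library_path
        self.multi_reactant_policy = multi_reactant_policy
        self.dedup_scope = dedup_scope
        self.exclude_parent = exclude_parent
        self.apply_filter = apply_filter
        self.use_screen = use_screen

    def fit(self, X: Sequence[ReactionRecord], y=None):
        """Build the template and substructure database from reactions."""
        library = annotation.load_fg_library(self.fg_library_path)
        self.templates_, self.substructures_, self.skip_report_ = (
            templates.build_template_db(
                list(X), library, apply_filter=self.apply_filter
            )
        )
        return self

    def transform(self, X: Iterable[str | engine.QueryCompound]) -> pd.DataFrame:
        """Enumerate transformation products for query SMILES."""
        check_is_fitted(self, "templates_")
        queries = [
            q if isinstance(q, engine.QueryCompound)
            else engine.QueryCompound(f"Q{i + 1}", q)
            for i, q in enumerate(X)
        ]
        frame, self.summary_ = engine.transform(
            queries,
            self.templates_,
            self.substructures_,
            multi_reactant_policy=self.multi_reactant_policy,
            dedup_scope=self.dedup_scope,
            exclude_parent=self.exclude_parent,
            use_screen=self.use_screen,
        )
        return frame


class ReactionAnnotator(BaseEstimator, TransformerMixin):
    """Stateless transformer: mapped reaction SMILES → annotation table."""

    def __init__(
        self,
        fg_library_path: str | None = None,
        class_rules_path: str | None = None,
    ):
        self.fg_library_path = fg_library_path
        self.class_rules_path = class_rules_path

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[str | ReactionRecord]) -> pd.DataFrame:
        library = annotation.load_fg_library(self.fg_library_path)
        rules = annotation.load_class_rules(self.class_rules_path)
        rows = []
        for i, item in enumerate(X):
            if isinstance(item, ReactionRecord):
                rxn_id, smi = item.rxn_id, item.mapped_reaction_smiles
            else:
                rxn_id, smi = f"R{i + 1}", item
            try:
                mapped = sanitize_mapped_reaction(smi or "", rxn_id)
            except SanitizationError as exc:
                rows.append({"RXN_ID": rxn_id, "SANITIZED": False,
                             "ERROR": str(exc)})
                continue
            ann = annotation.annotate_reaction(mapped, library, rules)
            rows.append(
                {
                    "RXN_ID": rxn_id,
                    "SANITIZED": True,
                    "CLASS": ann.class_label,
                    "FG_REACTANTS": "|".join(sorted(ann.fg_reactants.elements())),
                    "FG_PRODUCTS": "|".join(sorted(ann.fg_products.elements())),
                    "NOS_IN_CENTER": ann.nos_in_center,
                    "RING_IN_CENTER": ann.ring_in_center,
                    "RING_CHANGED": ann.ring_changed,
                    "HAS_SCAFFOLD": ann.has_scaffold,
                    "N_REACTANTS": ann.n_reactants,
                    "N_PRODUCTS": ann.n_products,
                    "N_SPECTATORS": len(ann.spectators),
                    "ERROR": "",
                }
            )
        return pd.DataFrame(rows)


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """SMILES list → descriptor DataFrame via a registered plugin."""

    def __init__(self, plugin: str = "physchem"):
        self.plugin = plugin

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[str]) -> pd.DataFrame:
        return prioritize.compute_descriptors(list(X), plugin=self.plugin)

    def get_feature_names_out(self, input_features=None):
        import numpy as np

        probe = prioritize.compute_descriptors(["C"], plugin=self.plugin)
        return np.asarray(probe.columns, dtype=object)


class ExtremeFlagger(BaseEstimator, TransformerMixin):
    """Flag descriptor profiles in the adverse-direction extreme tail.

    Fit stores the reference descriptor distribution (a DataFrame of
    descriptor columns, or a SMILES list to be profiled with ``plugin``);
    transform returns the profiles with percentile columns and flags.
    """

    def __init__(
        self,
        threshold: float = 1.0,
        directions: Mapping[str, str] | None = None,
        plugin: str = "physchem",
    ):
        self.threshold = threshold
        self.directions = directions
        self.plugin = plugin

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.reference_ = X.copy()
        else:
            self.reference_ = prioritize.compute_descriptors(
                list(X), plugin=self.plugin
            )
        if self.reference_.empty:
            raise ValueError("reference set is empty")
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        profiles = (
            X
            if isinstance(X, pd.DataFrame)
            else prioritize.compute_descriptors(list(X), plugin=self.plugin)
        )
        return prioritize.flag_extremes(
            profiles,
            self.reference_,
            threshold=self.threshold,
            directions=self.directions,
        )
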