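"""Scikit-learn style estimators: the primary user-facing surface.

``Anonymizer`` is a transformer: ``fit`` searches the generalization lattice
for the scheme (or, with local recoding, schemes) that maximizes
post-suppression granularity quality under the chosen privacy model, and
``transform`` recodes a table accordingly.  ``PitmanRiskEstimator`` fits the
two-parameter Poisson-Dirichlet model to the equivalence-class histogram of a
table and estimates population uniqueness.

Both follow the scikit-learn conventions (``get_params`` / ``set_params``,
fitted attributes with a trailing underscore, ``fit_transform`` via
``TransformerMixin``) and accept pandas DataFrames of strings.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import (AttributeDefinition, Dataset, GeneralizationHierarchy,
                         Role, read_hierarchy)
from .local import LocalRecodingConfig, anonymize_local
from .privacy import (KAnonymity, PopulationUniqueness, estimate_population_uniqueness,
                      fit_pitman)
from .search import (EXHAUSTIVE_CAP, AnonymizationContext, GAConfig,
                     SearchBudget, run_search)
from .transform import (apply_scheme, equivalence_classes, quality_granularity,
                        suppress_to_satisfy)

__all__ = ["Anonymizer", "PitmanRiskEstimator", "anonymize", "estimate_uniqueness"]


def _as_dataset(X, hierarchies: Mapping[str, GeneralizationHierarchy]) -> Dataset:
    if isinstance(X, Dataset):
        return X
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame of strings or a Dataset")
    frame = X.astype(object)
    attrs = tuple(
        AttributeDefinition(str(c), Role.QUASI_IDENTIFYING, hierarchies[str(c)])
        if str(c) in hierarchies else AttributeDefinition(str(c))
        for c in frame.columns)
    return Dataset(attrs, frame)


def _load_hierarchies(
    hierarchies: Mapping[str, GeneralizationHierarchy | str] | None,
    hierarchy_delimiter: str,
) -> dict[str, GeneralizationHierarchy]:
    out: dict[str, GeneralizationHierarchy] = {}
    for name, h in (hierarchies or {}).items():
        if isinstance(h, GeneralizationHierarchy):
            out[name] = h
        else:
            out[name] = read_hierarchy(h, delimiter=hierarchy_delimiter,
                                       attribute=name)
    return out


class Anonymizer(TransformerMixin, BaseEstimator):
    """Hierarchy-based anonymizer with lattice search.

    Parameters
    ----------
    hierarchies:
        Mapping from quasi-identifying column name to its generalization
        hierarchy (or a hierarchy file path).  Columns not listed are passed
        through untouched and ignored by the privacy model.
    privacy:
        ``"k_anonymity"`` (threshold ``k``) or ``"population_uniqueness"``
        (``uniqueness_threshold`` on the estimated population-unique fraction,
        with ``sampling_fraction`` giving the share of the population sampled).
    algorithm:
        ``"exhaustive"`` (small lattices only), ``"bottom_up"``,
        ``"top_down"``, or ``"genetic"``.
    recoding:
        ``"global"`` applies one scheme to all records; ``"local"`` runs the
        iterative partition loop (up to ``local_iterations`` rounds).
    time_limit, max_evaluations:
        Search budget, checked between scheme evaluations.
    ga_config:
        :class:`~anonlattice.search.GAConfig`; defaults match the published
        parameterization (subpopulations of 50, 50 iterations, ...).
    random_state:
        Seed for the genetic algorithm; ignored by the deterministic searches.

    Attributes
    ----------
    best_scheme_ : tuple of int or None
        Optimal generalization scheme found (None under local recoding).
    quality_ : float
        Granularity quality (percent) of the fitted output.
    n_suppressed_ : int
        Records suppressed in the fitted output.
    result_ : AnonymizationResult
        Full search result including the trace.
    """

    def __init__(self, hierarchies=None, *, privacy="k_anonymity", k=5,
                 uniqueness_threshold=0.01, sampling_fraction=1.0,
                 algorithm="top_down", recoding="global", local_iterations=100,
                 time_limit=None, max_evaluations=None, ga_config=None,
                 exhaustive_cap=EXHAUSTIVE_CAP, suppression_token="*",
                 hierarchy_delimiter=";", random_state=0):
        self.hierarchies = hierarchies
        self.privacy = privacy
        self.k = k
        self.uniqueness_threshold = uniqueness_threshold
        self.sampling_fraction = sampling_fraction
        self.algorithm = algorithm
        self.recoding = recoding
        self.local_iterations = local_iterations
        self.time_limit = time_limit
        self.max_evaluations = max_evaluations
        self.ga_config = ga_config
        self.exhaustive_cap = exhaustive_cap
        self.suppression_token = suppression_token
        self.hierarchy_delimiter = hierarchy_delimiter
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _model(self):
        if self.privacy == "k_anonymity":
            return KAnonymity(self.k)
        if self.privacy == "population_uniqueness":
            return PopulationUniqueness(self.uniqueness_threshold,
                                        self.sampling_fraction)
        raise ValueError(f"unknown privacy model {self.privacy!r}")

    def _budget(self) -> SearchBudget | None:
        if self.time_limit is None and self.max_evaluations is None:
            return None
        return SearchBudget(time_limit=self.time_limit,
                            max_evaluations=self.max_evaluations)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        """Search the lattice on ``X`` and store the best transformation."""
        hier = _load_hierarchies(self.hierarchies, self.hierarchy_delimiter)
        ds = _as_dataset(X, hier)
        if not ds.quasi_identifiers:
            raise ValueError("no quasi-identifying columns: supply hierarchies")
        model = self._model()
        if self.recoding == "local":
            cfg = LocalRecodingConfig(iterations=self.local_iterations,
                                      inner_algorithm=self.algorithm,
                                      per_iteration_budget=self._budget())
            result = anonymize_local(ds, model, cfg, ga_config=self.ga_config,
                                     seed=self.random_state,
                                     suppression_token=self.suppression_token)
        elif self.recoding == "global":
            ctx = AnonymizationContext(ds, model, self.suppression_token)
            result = run_search(ctx, self.algorithm, budget=self._budget(),
                                ga_config=self.ga_config, seed=self.random_state,
                                exhaustive_cap=self.exhaustive_cap)
        else:
            raise ValueError(f"recoding must be 'global' or 'local', "
                             f"got {self.recoding!r}")
        self.dataset_ = ds
        self.result_ = result
        self.best_scheme_ = result.scheme
        self.quality_ = result.quality
        self.n_suppressed_ = result.n_suppressed
        self.n_evaluations_ = result.evaluations
        self.feature_names_in_ = list(ds.frame.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Recode ``X`` with the fitted transformation.

        Under global recoding the fitted scheme is applied and suppression is
        re-evaluated on ``X`` (for the training table this reproduces the
        fitted output exactly).  Local recoding learns per-partition schemes
        that are tied to the fitted records, so it only transforms the
        training table.
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("Anonymizer is not fitted")
        if self.recoding == "local":
            fitted = self.dataset_.frame
            if not (isinstance(X, pd.DataFrame) and fitted.equals(X.astype(object))):
                raise ValueError(
                    "local recoding defines per-record schemes; transform() "
                    "accepts only the fitted table")
            assert self.result_.transformed is not None
            return self.result_.transformed.frame.copy()
        hier = _load_hierarchies(self.hierarchies, self.hierarchy_delimiter)
        ds = _as_dataset(X, hier)
        t = apply_scheme(ds, self.best_scheme_, self.suppression_token)
        t = suppress_to_satisfy(t, self._model())
        return t.frame


class PitmanRiskEstimator(BaseEstimator):
    """Population-uniqueness risk via the Pitman (Poisson-Dirichlet) model.

    ``fit`` computes the equivalence-class histogram of the quasi-identifying
    columns, fits PD(alpha, theta) by method of moments, and stores the
    estimated fraction of the population unique on those columns.

    Parameters
    ----------
    quasi_identifiers:
        Column names treated as quasi-identifying (default: all columns).
    sampling_fraction:
        Share of the population contained in the table, in (0, 1].
    """

    def __init__(self, quasi_identifiers: Sequence[str] | None = None, *,
                 sampling_fraction: float = 1.0):
        self.quasi_identifiers = quasi_identifiers
        self.sampling_fraction = sampling_fraction

    def fit(self, X, y=None):
        if isinstance(X, Dataset):
            frame = X.frame
            qi = list(X.qi_names) or list(frame.columns)
        else:
            frame = pd.DataFrame(X).astype(object)
            qi = list(self.quasi_identifiers or frame.columns)
        counts = frame.groupby(qi, sort=False, dropna=False).size() \
            if len(frame) else pd.Series(dtype=int)
        from .transform import EquivalenceClassHistogram
        hist = EquivalenceClassHistogram(tuple(int(c) for c in counts))
        self.histogram_ = hist
        self.n_classes_ = hist.n_classes
        self.n_singletons_ = hist.n_singletons
        if hist.n_effective == 0:
            self.theta_, self.alpha_, self.converged_ = 0.0, 0.0, False
            self.uniqueness_ = 0.0
            return self
        pit = fit_pitman(hist)
        self.theta_, self.alpha_, self.converged_ = \
            pit.theta, pit.alpha, pit.converged
        self.uniqueness_ = estimate_population_uniqueness(
            hist, self.sampling_fraction)
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def anonymize(X, hierarchies, **params) -> Anonymizer:
    """Fit an :class:`Anonymizer` on ``X`` and return it."""
    return Anonymizer(hierarchies, **params).fit(X)


def estimate_uniqueness(X, quasi_identifiers=None,
                        sampling_fraction: float = 1.0) -> float:
    """Estimated population-unique fraction of ``X`` on the given columns."""
    est = PitmanRiskEstimator(quasi_identifiers,
                              sampling_fraction=sampling_fraction).fit(X)
    return est.uniqueness_
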