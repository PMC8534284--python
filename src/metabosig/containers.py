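"""Core in-memory containers shared by every analysis stage.

The central object is :class:`FeatureMatrix` — a samples × features table of
metabolite intensities or absolute concentrations — together with per-sample
metadata, pooled-QC series, and the network / signature / model result types
produced downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

#: Allowed scale states of a feature matrix, in pipeline order.
SCALE_STATES = ("raw", "log", "log-pareto")

Edge = FrozenSet[str]


def edge(a: str, b: str) -> Edge:
    """Canonical unordered node pair (no self-loops allowed)."""
    if a == b:
        raise ValueError(f"self-loop edge on node {a!r}")
    return frozenset((a, b))


@dataclass
class FeatureMatrix:
    """Samples × metabolite-features grid with a tracked scale state.

    Parameters
    ----------
    values
        DataFrame with sample IDs in the index and feature IDs in the
        columns. NaN encodes missing measurements.
    scale_state
        One of ``"raw"`` (non-negative intensities/concentrations),
        ``"log"`` (log2) or ``"log-pareto"`` (log2, mean-centred, divided
        by the square root of the feature standard deviation).
    """

    values: pd.DataFrame
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(
                f"scale_state must be one of {SCALE_STATES}, got {self.scale_state!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.scale_state == "raw":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise ValueError("raw-scale values must be >= 0 where observed")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(sample_ids)].copy(), self.scale_state)

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(feature_ids)].copy(), self.scale_state)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.scale_state)


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates.

    ``table`` columns: ``group`` in {control, case}, ``sex`` in {F, M},
    ``age`` (years), and optionally ``cfdna`` (ng/mL). The index holds the
    sample IDs and must match the companion :class:`FeatureMatrix`.
    """

    table: pd.DataFrame

    REQUIRED = ("group", "sex", "age")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad_group = set(self.table["group"]) - {"control", "case"}
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(self.table["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.table.index)

    def group_mask(self, group: str) -> pd.Series:
        return self.table["group"] == group

    def samples_in_group(self, group: str) -> List[str]:
        return list(self.table.index[self.group_mask(group)])

    @property
    def cfdna(self) -> Optional[pd.Series]:
        return self.table["cfdna"] if "cfdna" in self.table.columns else None


@dataclass
class QCSeries:
    """Pooled-QC replicate injections and dilution-series intensities.

    replicate_intensities : feature ID -> repeated pooled-QC intensities
    dilution_intensities  : feature ID -> list of (dilution fraction, intensity)
    """

    replicate_intensities: Dict[str, List[float]]
    dilution_intensities: Dict[str, List[Tuple[float, float]]]

    def __post_init__(self) -> None:
        for fid, pts in self.dilution_intensities.items():
            if any(d <= 0 for d, _ in pts):
                raise ValueError(f"non-positive dilution fraction for feature {fid!r}")

    @property
    def feature_ids(self) -> List[str]:
        ids = set(self.replicate_intensities) | set(self.dilution_intensities)
        return sorted(ids)


@dataclass
class MetabolicNetwork:
    """Undirected network over metabolite nodes.

    A network is its edge-supported subgraph: nodes without an incident
    edge are not part of the network. ``weights`` maps each edge to a
    signed strength (partial correlation for glasso networks, Spearman rho
    for correlation views).
    """

    nodes: Set[str] = field(default_factory=set)
    edges: Set[Edge] = field(default_factory=set)
    weights: Dict[Edge, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)} is not a 2-node pair")
            if not e <= self.nodes:
                raise ValueError(f"edge {set(e)} references unknown nodes")
        if self.weights and set(self.weights) != self.edges:
            raise ValueError("weights must be defined for exactly the edge set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(provenance=self.provenance)
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges, key=sorted):
            a, b = sorted(e)
            attrs = {"weight": self.weights[e]} if self.weights else {}
            g.add_edge(a, b, **attrs)
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        weights: Optional[Dict[Edge, float]] = None,
        provenance: str = "",
    ) -> "MetabolicNetwork":
        eset = {edge(a, b) for a, b in edges}
        nodes = set().union(*eset) if eset else set()
        w = {e: weights[e] for e in eset} if weights else {}
        return cls(nodes=nodes, edges=eset, weights=w, provenance=provenance)


@dataclass
class PatientSignature:
    """Node set of one patient-specific (double-pruned) network."""

    patient_id: str
    metabolite_set: Set[str]


@dataclass
class ConsensusSignature:
    """Per-metabolite signature frequencies and the thresholded selection.

    ``frequencies[m]`` is the fraction of patient signatures containing
    metabolite ``m``; ``selected`` keeps metabolites with frequency
    strictly above ``threshold``.
    """

    frequencies: Dict[str, float]
    threshold: float
    selected: Set[str]
    n_signatures: int


@dataclass
class SubsetModelResult:
    """Random-forest screen result for one metabolite subset."""

    subset: Tuple[str, ...]
    auc: float
    ci_low: float
    ci_high: float
    n_repeats: int
    per_repeat_aucs: List[float]
    is_full_model: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise ValueError("AUC confidence interval must bracket the mean AUC in [0,1]")
        if self.n_repeats != len(self.per_repeat_aucs):
            raise ValueError("n_repeats must equal the number of per-repeat AUCs")
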