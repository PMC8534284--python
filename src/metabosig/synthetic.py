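"""Synthetic glioblastoma-style metabolomics cohorts with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: a targeted-panel plasma cohort (60 controls vs 22 cases by
default) and a small matched tissue cohort (6 controls vs 22 cases) over
188 metabolite features spanning the classic targeted-panel classes
(acylcarnitines, amino acids, biogenic amines, hexose,
phosphatidylcholines, sphingomyelins). Data are multivariate log-normal:
Gaussian on the log2 scale with a block-sparse precision matrix, so the
conditional-independence graph of the log-transformed data is known
exactly. Case samples additionally receive planted mean shifts on a DE
subset and a planted case-only conditional-dependence module (the ground
truth for the consensus-signature procedure), cfDNA coupled to chosen
metabolites through a Gaussian copula, completely-at-random missingness,
and a pooled-QC replicate/dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Edge, FeatureMatrix, QCSeries, SampleMetadata, edge

__all__ = [
    "CLASS_LAYOUT",
    "SimulationConfig",
    "SyntheticTruth",
    "feature_panel",
    "build_precisions",
    "simulate_ggm",
    "simulate_cohort",
    "simulate_qc_series",
    "spike_cfdna",
]

#: Feature-class layout of a 188-metabolite targeted panel.
CLASS_LAYOUT: Dict[str, Tuple[str, int]] = {
    "acylcarnitine": ("AC", 40),
    "amino_acid": ("AA", 21),
    "biogenic_amine": ("BA", 21),
    "hexose": ("HEX", 1),
    "phosphatidylcholine": ("PC", 90),
    "sphingomyelin": ("SM", 15),
}


@dataclass
class SimulationConfig:
    """Everything the cohort generator needs, with study-shaped defaults.

    Cohort sizes follow the study design (plasma 60 control / 22 case,
    tissue 6 control / 22 case, 188 features). ``effect_sizes`` maps
    feature ID -> case shift in log2 units; when None, ``n_de_features``
    features receive ``default_effect_size``. ``precision_spec`` may
    supply an explicit symmetric positive-definite precision matrix
    (features x features); by default a block-sparse precision over the
    panel classes is built with partial correlations of
    ``control_partial_corr``. ``planted_consensus`` names the metabolites
    whose case-only dependence module is planted (default: 6
    phosphatidylcholines + 2 sphingomyelins). Log-scale feature standard
    deviations are chosen so that raw-scale median CVs land near 36%
    (plasma) and 127% (tissue), reproducing the plasma/tissue
    heterogeneity contrast.
    """

    n_control_plasma: int = 60
    n_case_plasma: int = 22
    n_control_tissue: int = 6
    n_case_tissue: int = 22
    n_features: int = 188
    n_de_features: int = 8
    default_effect_size: float = 2.0
    effect_sizes: Optional[Dict[str, float]] = None
    precision_spec: Optional[np.ndarray] = None
    planted_consensus: Optional[Set[str]] = None
    n_consensus: int = 8
    cfdna_targets: Optional[Dict[str, float]] = None
    missing_rate: float = 0.02
    qc_replicates: int = 8
    dilution_factors: Tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625)
    noise_cv: float = 0.10
    control_partial_corr: float = 0.30
    factor_loading_range: Tuple[float, float] = (2.4, 2.6)
    plasma_log_sd: float = 0.50
    tissue_log_sd: float = 1.40
    control_age: Tuple[float, float] = (34.0, 10.0)
    case_age: Tuple[float, float] = (62.0, 9.0)
    case_male_fraction: float = 0.82
    seed: int = 0

    def validate(self, feature_ids: Sequence[str]) -> None:
        if self.n_de_features > self.n_features:
            raise ValueError("n_de_features cannot exceed n_features")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        d = self.dilution_factors
        if any(not (0 < x <= 1) for x in d) or any(a <= b for a, b in zip(d, d[1:])):
            raise ValueError("dilution factors must be strictly decreasing in (0, 1]")
        if self.effect_sizes:
            unknown = set(self.effect_sizes) - set(feature_ids)
            if unknown:
                raise ValueError(f"effect sizes for unknown features: {sorted(unknown)}")
        if self.cfdna_targets and any(abs(r) >= 1 for r in self.cfdna_targets.values()):
            raise ValueError("cfDNA target rho values must lie in (-1, 1)")
        if self.precision_spec is not None:
            check_precision(np.asarray(self.precision_spec, dtype=float))


@dataclass
class SyntheticTruth:
    """Everything planted into a simulated cohort."""

    true_de_set: Set[str]
    effect_sizes: Dict[str, float]
    true_edge_set: Set[Edge]
    case_only_edges: Set[Edge]
    true_consensus_set: Set[str]
    annotations: Dict[str, str]
    generating_parameters: SimulationConfig

    def __post_init__(self) -> None:
        if self.case_only_edges & self.true_edge_set:
            raise ValueError("case-only edges must be disjoint from the control edge set")


def feature_panel(n_features: int = 188) -> Tuple[List[str], Dict[str, str]]:
    """Feature IDs and class annotations for an n-feature targeted panel.

    The 188-feature default reproduces the class layout of the targeted
    kit; other sizes scale the classes proportionally.
    """
    ids: List[str] = []
    annotations: Dict[str, str] = {}
    total = sum(n for _, n in CLASS_LAYOUT.values())
    remaining = n_features
    items = list(CLASS_LAYOUT.items())
    for idx, (cls, (prefix, n)) in enumerate(items):
        count = remaining if idx == len(items) - 1 else min(remaining, round(n * n_features / total))
        for i in range(count):
            fid = f"{prefix}_{i + 1:03d}"
            ids.append(fid)
            annotations[fid] = cls
        remaining -= count
    return ids, annotations


def check_precision(theta: np.ndarray) -> None:
    """Reject asymmetric or non-positive-definite precision matrices."""
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(theta, theta.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    eigmin = float(np.linalg.eigvalsh(theta)[0])
    if eigmin <= 0:
        raise ValueError(
            f"precision matrix is not positive definite (smallest eigenvalue {eigmin:.3e})"
        )


def _budgeted_edges(
    nodes: Sequence[str],
    rng: np.random.Generator,
    strength: float,
    budget: float = 0.95,
    edges_per_node: float = 1.0,
) -> Set[Edge]:
    """Random within-class edges under a diagonal-dominance budget.

    Each node can spend at most ``budget`` of absolute off-diagonal mass,
    which keeps the unit-diagonal precision strictly diagonally dominant
    and therefore positive definite, with partial correlations exactly
    equal to ``strength`` on every accepted edge.
    """
    spent = {n: 0.0 for n in nodes}
    edges: Set[Edge] = set()
    n_target = int(edges_per_node * len(nodes))
    nodes = list(nodes)
    for _ in range(n_target * 4):
        if len(edges) >= n_target:
            break
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        e = edge(a, b)
        if e in edges or spent[a] + strength > budget or spent[b] + strength > budget:
            continue
        edges.add(e)
        spent[a] += strength
        spent[b] += strength
    return edges


def _precision_from_edges(
    feature_ids: Sequence[str], weighted_edges: Dict[Edge, float]
) -> np.ndarray:
    idx = {f: i for i, f in enumerate(feature_ids)}
    theta = np.eye(len(feature_ids))
    for e, rho in weighted_edges.items():
        a, b = sorted(e)
        theta[idx[a], idx[b]] = theta[idx[b], idx[a]] = -rho
    check_precision(theta)
    return theta


def build_precisions(
    config: SimulationConfig,
    feature_ids: Sequence[str],
    annotations: Dict[str, str],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Set[Edge], Set[Edge], Set[str]]:
    """Control precision matrix plus the planted edge/consensus truth.

    The control precision is block-sparse within metabolite classes with
    partial correlation ``control_partial_corr``; consensus members carry
    no control edges. Case-only dependence among the consensus members is
    generated at sampling time by a patient-specific latent factor (see
    :func:`simulate_cohort`), which couples every pair of members — the
    case-only edge truth is therefore all pairwise combinations of the
    consensus set.
    """
    if config.planted_consensus is not None:
        consensus_set = set(config.planted_consensus)
        unknown = consensus_set - set(feature_ids)
        if unknown:
            raise ValueError(f"planted consensus features not in panel: {sorted(unknown)}")
    else:
        pcs = [f for f in feature_ids if annotations[f] == "phosphatidylcholine"]
        sms = [f for f in feature_ids if annotations[f] == "sphingomyelin"]
        n_pc = min(6, config.n_consensus, len(pcs))
        n_sm = min(config.n_consensus - n_pc, len(sms))
        consensus_set = {str(f) for f in rng.choice(pcs, size=n_pc, replace=False)} | {
            str(f) for f in rng.choice(sms, size=n_sm, replace=False)
        }
    members = sorted(consensus_set)

    control_edges: Set[Edge] = set()
    by_class: Dict[str, List[str]] = {}
    for fid in feature_ids:
        by_class.setdefault(annotations[fid], []).append(fid)
    for cls, nodes in by_class.items():
        free = [n for n in nodes if n not in consensus_set]
        if len(free) >= 2:
            control_edges |= _budgeted_edges(free, rng, config.control_partial_corr)

    case_only = {edge(a, b) for i, a in enumerate(members) for b in members[i + 1 :]}
    case_only -= control_edges
    weighted = {e: config.control_partial_corr for e in control_edges}
    theta_control = (
        np.asarray(config.precision_spec, dtype=float)
        if config.precision_spec is not None
        else _precision_from_edges(feature_ids, weighted)
    )
    return theta_control, control_edges, case_only, consensus_set


def simulate_ggm(
    precision_spec: Union[np.ndarray, pd.DataFrame],
    n_samples: int,
    seed: int,
    feature_ids: Optional[Sequence[str]] = None,
    sample_prefix: str = "S",
) -> FeatureMatrix:
    """Zero-mean multivariate-normal draws with a known precision matrix.

    The sample conditional-dependence structure converges to the nonzero
    pattern of ``precision_spec`` as n grows; used as the exact oracle
    for graphical-lasso network estimation.
    """
    if isinstance(precision_spec, pd.DataFrame):
        feature_ids = feature_ids or list(precision_spec.columns)
        precision_spec = precision_spec.to_numpy(dtype=float)
    theta = np.asarray(precision_spec, dtype=float)
    check_precision(theta)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p = theta.shape[0]
    if feature_ids is None:
        feature_ids = [f"V{i + 1}" for i in range(p)]
    cov = np.linalg.inv(theta)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_samples, p)) @ chol.T
    df = pd.DataFrame(
        z, index=[f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)], columns=list(feature_ids)
    )
    return FeatureMatrix(df, scale_state="log")


def _draw_ages(rng: np.random.Generator, n: int, loc_scale: Tuple[float, float]) -> np.ndarray:
    loc, scale = loc_scale
    return np.clip(np.round(rng.normal(loc, scale, size=n)), 18, 90)


def _log_to_raw_matrix(
    z: np.ndarray, baselines: np.ndarray, log_sd: float, sample_ids: List[str],
    feature_ids: Sequence[str], effects: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    log2_vals = baselines + log_sd * z
    if effects is not None:
        log2_vals = log2_vals + effects
    df = pd.DataFrame(2.0**log2_vals, index=sample_ids, columns=list(feature_ids))
    return FeatureMatrix(df, scale_state="raw")


def _inject_mcar(matrix: FeatureMatrix, rate: float, rng: np.random.Generator) -> FeatureMatrix:
    if rate <= 0:
        return matrix
    vals = matrix.values.to_numpy(dtype=float).copy()
    mask = rng.random(vals.shape) < rate
    # keep every feature observed at least once per compartment
    for j in np.where(mask.all(axis=0))[0]:
        mask[rng.integers(vals.shape[0]), j] = False
    vals[mask] = np.nan
    return FeatureMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        scale_state="raw",
    )


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[FeatureMatrix, FeatureMatrix, SampleMetadata, QCSeries, SyntheticTruth]:
    """Generate the full synthetic study: plasma, tissue, metadata, QC, truth.

    Case samples receive the planted log2 mean shifts on the DE set; a
    patient-specific latent factor with heterogeneous loadings on the
    consensus members creates the case-only dependence module and the
    inter-patient heterogeneity that the leave-one-out signature
    procedure fingerprints. Ages and sex reproduce the cohort summary
    (control median age ~34, case ~62, ~82% male cases); cfDNA is
    coupled to the target metabolites by a Gaussian copula; missing
    entries are MCAR.
    """
    feature_ids, annotations = feature_panel(config.n_features)
    config.validate(feature_ids)
    rng = np.random.default_rng(config.seed)

    theta_c, control_edges, case_only, consensus_set = build_precisions(
        config, feature_ids, annotations, rng
    )

    if config.effect_sizes is not None:
        effects = dict(config.effect_sizes)
    else:
        # planted mean shifts live outside the dependence module, so the
        # two kinds of planted signal can be recovered independently
        pool = [f for f in feature_ids if f not in consensus_set]
        effects = {
            str(f): config.default_effect_size
            for f in rng.choice(pool, size=config.n_de_features, replace=False)
        }
    de_set = {f for f, v in effects.items() if v != 0}

    p = len(feature_ids)
    baselines = rng.uniform(10.0, 20.0, size=p)
    effect_vec = np.array([effects.get(f, 0.0) for f in feature_ids])
    chol_c = np.linalg.cholesky(np.linalg.inv(theta_c))
    members = sorted(consensus_set)
    member_idx = [feature_ids.index(m) for m in members]
    lo, hi = config.factor_loading_range
    loadings = np.zeros(p)
    if members:
        loadings[member_idx] = rng.uniform(lo, hi, size=len(members))

    def draw(n: int, case: bool) -> np.ndarray:
        z = rng.standard_normal((n, p)) @ chol_c.T
        if case and members:
            # Shared per-tumor dysregulation factor: creates the case-only
            # dependence module among the consensus members (within-case
            # pairwise correlation b^2/(1+b^2), ~0.86 at the default
            # loadings) while the control distribution is untouched.
            activity = rng.standard_normal(n)
            z = z + np.outer(activity, loadings)
        return z

    ids_cp = [f"P_CTRL_{i + 1:03d}" for i in range(config.n_control_plasma)]
    ids_dp = [f"P_GBM_{i + 1:03d}" for i in range(config.n_case_plasma)]
    ids_ct = [f"T_CTRL_{i + 1:03d}" for i in range(config.n_control_tissue)]
    ids_dt = [f"T_GBM_{i + 1:03d}" for i in range(config.n_case_tissue)]

    plasma_vals = pd.concat(
        [
            _log_to_raw_matrix(draw(len(ids_cp), False), baselines, config.plasma_log_sd, ids_cp, feature_ids).values,
            _log_to_raw_matrix(draw(len(ids_dp), True), baselines, config.plasma_log_sd, ids_dp, feature_ids, effect_vec).values,
        ]
    )
    tissue_vals = pd.concat(
        [
            _log_to_raw_matrix(draw(len(ids_ct), False), baselines, config.tissue_log_sd, ids_ct, feature_ids).values,
            _log_to_raw_matrix(draw(len(ids_dt), True), baselines, config.tissue_log_sd, ids_dt, feature_ids, effect_vec).values,
        ]
    )
    plasma = FeatureMatrix(plasma_vals, scale_state="raw")
    tissue = FeatureMatrix(tissue_vals, scale_state="raw")

    rows = []
    for sid in ids_cp + ids_ct:
        age_pool = config.control_age
        rows.append((sid, "control", "M" if rng.random() < 0.5 else "F", float(_draw_ages(rng, 1, age_pool)[0]), "plasma" if sid.startswith("P") else "tissue"))
    for sid in ids_dp + ids_dt:
        rows.append((sid, "case", "M" if rng.random() < config.case_male_fraction else "F", float(_draw_ages(rng, 1, config.case_age)[0]), "plasma" if sid.startswith("P") else "tissue"))
    meta_df = pd.DataFrame(rows, columns=["sample_id", "group", "sex", "age", "compartment"]).set_index("sample_id")
    metadata = SampleMetadata(meta_df)

    if config.cfdna_targets is not None:
        cfdna_targets = dict(config.cfdna_targets)
    else:
        # pick conditionally independent (edge-free) targets so the joint
        # copula construction stays feasible at any realisation
        linked = set().union(*control_edges) if control_edges else set()
        free = [
            f for f in feature_ids
            if f not in linked and f not in consensus_set and f not in de_set
        ]
        by_cls = {c: [f for f in free if annotations[f] == c] for c in
                  ("amino_acid", "acylcarnitine", "biogenic_amine")}
        wanted = [("amino_acid", 0.50), ("acylcarnitine", 0.45), ("biogenic_amine", -0.60)]
        cfdna_targets = {
            str(rng.choice(by_cls[c])): r for c, r in wanted if by_cls[c]
        }
    plasma_meta = SampleMetadata(meta_df.loc[ids_cp + ids_dp].copy())
    plasma_meta = spike_cfdna(
        plasma_meta, plasma, cfdna_targets, seed=int(rng.integers(2**31 - 1))
    )
    meta_df["cfdna"] = np.nan
    meta_df.loc[plasma_meta.table.index, "cfdna"] = plasma_meta.table["cfdna"]
    metadata = SampleMetadata(meta_df)

    plasma = _inject_mcar(plasma, config.missing_rate, rng)
    tissue = _inject_mcar(tissue, config.missing_rate, rng)

    qc = simulate_qc_series(config, None, seed=int(rng.integers(2**31 - 1)), baselines=dict(zip(feature_ids, 2.0**baselines)))

    truth = SyntheticTruth(
        true_de_set=de_set,
        effect_sizes=effects,
        true_edge_set=control_edges,
        case_only_edges=case_only,
        true_consensus_set=consensus_set,
        annotations=annotations,
        generating_parameters=config,
    )
    return plasma, tissue, metadata, qc, truth


def simulate_qc_series(
    config: SimulationConfig,
    feature_behaviors: Optional[Dict[str, str]] = None,
    seed: int = 0,
    baselines: Optional[Dict[str, float]] = None,
) -> QCSeries:
    """Pooled-QC replicate and dilution-series intensities.

    ``feature_behaviors`` labels each feature ``"well"`` (intensity
    proportional to dilution, replicate CV = ``config.noise_cv``),
    ``"flat"`` (no dilution response), or ``"noisy"`` (responds to
    dilution but replicate CV of 0.5). Well-behaved features pass both QC
    filters; flat features fail the dilution-correlation filter and noisy
    ones fail the RSD filter with high probability.
    """
    if len(config.dilution_factors) < 3:
        raise ValueError("need >= 3 dilution points for the correlation filter")
    if baselines is None:
        feature_ids, _ = feature_panel(config.n_features)
        rng0 = np.random.default_rng(config.seed)
        baselines = dict(zip(feature_ids, 2.0 ** rng0.uniform(10, 20, size=len(feature_ids))))
    behaviors = feature_behaviors or {f: "well" for f in baselines}
    rng = np.random.default_rng(seed)
    NOISY_CV = 0.5
    replicates: Dict[str, List[float]] = {}
    dilutions: Dict[str, List[Tuple[float, float]]] = {}
    for fid, kind in behaviors.items():
        base = baselines[fid]
        if kind not in ("well", "flat", "noisy"):
            raise ValueError(f"unknown QC behavior {kind!r} for feature {fid!r}")
        cv = NOISY_CV if kind == "noisy" else config.noise_cv
        reps = base * (1.0 + cv * rng.standard_normal(config.qc_replicates))
        replicates[fid] = [float(max(v, 1e-9)) for v in reps]
        pts = []
        for d in config.dilution_factors:
            level = base if kind == "flat" else base * d
            pts.append((float(d), float(max(level * (1.0 + config.noise_cv * rng.standard_normal()), 1e-9))))
        dilutions[fid] = pts
    return QCSeries(replicate_intensities=replicates, dilution_intensities=dilutions)


def spike_cfdna(
    metadata: SampleMetadata,
    feature_matrix: FeatureMatrix,
    cfdna_targets: Optional[Dict[str, float]],
    seed: int = 0,
) -> SampleMetadata:
    """Attach a cfDNA concentration coupled to target metabolites.

    Coupling uses a Gaussian copula on rank-based normal scores of the
    target features: the latent cfDNA variable is a linear blend of the
    target scores whose coefficients solve for the requested (rank)
    correlations, then mapped monotonically to a log-normal ng/mL scale,
    which preserves Spearman correlation exactly.
    """
    rng = np.random.default_rng(seed)
    n = feature_matrix.n_samples
    targets = dict(cfdna_targets or {})
    for fid, r in targets.items():
        if fid not in feature_matrix.feature_ids:
            raise ValueError(f"cfDNA target {fid!r} not in the feature matrix")
        if abs(r) >= 1:
            raise ValueError(f"cfDNA target rho for {fid!r} must lie in (-1, 1)")
    if targets:
        scores = []
        for fid in targets:
            col = feature_matrix.values[fid].to_numpy(dtype=float)
            col = np.where(np.isnan(col), np.nanmedian(col), col)
            ranks = stats.rankdata(col)
            scores.append(stats.norm.ppf((ranks - 0.375) / (n + 0.25)))
        z = np.column_stack(scores)
        # Spearman -> Pearson for the bivariate normal copula
        rho_p = np.array([2.0 * np.sin(np.pi * r / 6.0) for r in targets.values()])
        c = np.corrcoef(z, rowvar=False) if z.shape[1] > 1 else np.ones((1, 1))
        coeffs = np.linalg.solve(c, rho_p)
        explained = float(rho_p @ coeffs)
        if explained >= 1.0 and any(abs(r) >= 0.95 for r in targets.values()):
            raise ValueError("cfDNA targets are jointly infeasible (explained variance >= 1)")
        if explained > 0.9:
            # sampling noise in the target-score correlations can push the
            # joint solve past unit variance; shrink all couplings
            # proportionally (a few percent on the realised rho)
            shrink = np.sqrt(0.9 / explained)
            coeffs = coeffs * shrink
            explained = 0.9
        latent = z @ coeffs + np.sqrt(1.0 - explained) * rng.standard_normal(n)
    else:
        latent = rng.standard_normal(n)
    cfdna = np.exp(2.3 + 0.6 * latent)  # median ~10 ng/mL
    table = metadata.table.copy()
    table.loc[feature_matrix.sample_ids, "cfdna"] = cfdna
    return SampleMetadata(table)
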