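"""Synthetic study inputs with known ground truth.

The original clinical and survey data are not publicly deposited, so every
input the pipeline consumes can be generated here under a controlled
generative model:

* **Expert score matrices** — ordinal Likert scores in {0..4} per
  (expert, item), drawn from a mean-matched binomial(4, p) mixed with a
  uniform component that widens dispersion.  Deliberately weak items (low
  mean, high dispersion) are planted so the consensus deletion rules have
  something to delete.
* **Clinical cohorts** — binary symptom indicators plus gender and a
  two-level age group; the diagnosis label follows a logistic model over a
  sparse informative-symptom support and an age effect, with the intercept
  calibrated so the cohort prevalence matches a target.  The planted
  support is returned as :class:`SyntheticTruth` for recovery tests.
* **Knowledge-base snapshots** — a phenotype-term -> gene annotation
  table, a STRING-style scored interaction edge list with planted
  high-degree hub genes, GMT pathway gene sets with planted hub
  enrichment, and a symptom -> term map including unmappable symptoms.

All randomness flows through an explicit integer seed; identical
(parameters, seed) give identical outputs, and the file writers emit
byte-identical snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .delphi import ExpertScoreMatrix

__all__ = [
    "ItemSpec",
    "ClinicalDataset",
    "SyntheticTruth",
    "KnowledgeBase",
    "CORE_SYMPTOMS",
    "NOISE_SYMPTOMS",
    "DEFAULT_SYMPTOMS",
    "DEFAULT_PREVALENCE",
    "default_truth",
    "generate_expert_scores",
    "default_expert_items",
    "generate_clinical_cohort",
    "generate_knowledge_base",
    "write_knowledge_base",
    "read_knowledge_base",
]

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: The 19 core symptoms of the syndrome (informative in the default cohort),
#: ordered by their planted effect size, largest first.
CORE_SYMPTOMS: tuple[str, ...] = (
    "Thick fur",
    "Dry stool",
    "Abnormal appetite",
    "Reduced frequency of defecation",
    "Restlessness at night sleep",
    "Halitosis",
    "Sweating at night",
    "Yellow fur",
    "Vexation and irritability",
    "Red tongue",
    "Slippery pulse",
    "Feverish feeling in palms and soles",
    "Smelly stool",
    "Worse after improper diet",
    "Yellow urine",
    "Red lips",
    "Vomiting",
    "Belching",
    "Hard defecation",
)

#: 18 additional collection-form symptoms carrying no diagnostic signal.
NOISE_SYMPTOMS: tuple[str, ...] = (
    "Red complexion",
    "Aversion to heat",
    "Head sweating",
    "Eye discharge",
    "Epistaxis",
    "Gingival swelling",
    "Gingival pain",
    "Hot mouth and nasal breath",
    "Mouth sores",
    "Thirst with preference for cold drink",
    "Vomiting with smell",
    "Distending pain in the abdomen",
    "Umbilical tenderness",
    "Gastric tenderness",
    "Smelly flatus",
    "Pharyngeal swelling",
    "Pharyngalgia",
    "Pharyngeal tonsil swelling",
)

DEFAULT_SYMPTOMS: tuple[str, ...] = CORE_SYMPTOMS + NOISE_SYMPTOMS

#: cohort prevalence of the positive diagnosis (453 of 660 subjects)
DEFAULT_PREVALENCE = 453 / 660
DEFAULT_N = 660

#: marginal probability of the younger (3-6 years) age group (316 of 660)
_P_AGE_YOUNG = 316 / 660
#: marginal probability of male gender (340 of 660)
_P_MALE = 340 / 660
#: log-odds shift of a positive diagnosis for the 3-6 age group
_AGE_EFFECT = 1.0
#: relative symptom-prevalence surplus of the 3-6 group (younger children
#: carry a higher symptom burden; calibrated so the marginal age-diagnosis
#: association matches the reference cohort's ~55% vs ~32% young fractions)
_AGE_PREV_DELTA = 0.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemSpec:
    """Target distribution of one survey item's expert scores.

    ``mu`` is the target mean on the 0-4 scale; ``kappa`` controls
    concentration (larger = tighter around the mean-matched binomial;
    ``math.inf`` = pure binomial).  ``planted_weak`` marks items meant to
    be deleted by the consensus rules.
    """

    label: str
    mu: float
    kappa: float = math.inf
    planted_weak: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 4.0:
            raise ValueError(f"item {self.label!r}: mu must be in [0, 4], got {self.mu}")
        if not self.kappa > 0:
            raise ValueError(f"item {self.label!r}: kappa must be positive, got {self.kappa}")


@dataclass
class ClinicalDataset:
    """Per-subject binary symptoms, covariates, and the diagnosis label.

    ``frame`` columns: subject_id, gender ('male'/'female'), age_group
    ('3-6'/'7-14'), one 0/1 column per symptom, and label
    ('positive'/'negative').  Complete cases only — no missing values.
    """

    frame: pd.DataFrame
    symptoms: list[str]

    def __post_init__(self) -> None:
        required = {"subject_id", "gender", "age_group", "label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"clinical frame missing columns: {sorted(missing)}")
        if self.frame[self.symptoms + ["label"]].isna().any().any():
            raise ValueError("clinical dataset must be complete-case (no missing values)")
        sym = self.frame[self.symptoms].to_numpy()
        if not np.isin(sym, (0, 1)).all():
            raise ValueError("symptom indicators must be 0/1")
        if not set(self.frame["label"]) <= {"positive", "negative"}:
            raise ValueError("labels must be 'positive'/'negative'")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """n x p binary symptom matrix (float)."""
        return self.frame[self.symptoms].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """0/1 label vector, 1 = positive diagnosis."""
        return (self.frame["label"] == "positive").to_numpy(dtype=int)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())

    def subset(self, index: np.ndarray) -> "ClinicalDataset":
        return ClinicalDataset(self.frame.iloc[index].reset_index(drop=True), list(self.symptoms))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClinicalDataset":
        frame = pd.read_csv(path)
        meta = {"subject_id", "gender", "age_group", "label"}
        symptoms = [c for c in frame.columns if c not in meta]
        return cls(frame=frame, symptoms=symptoms)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the cohort generative model."""

    informative_symptoms: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    age_effect: float

    def __post_init__(self) -> None:
        if set(self.informative_symptoms) != set(self.coefficients):
            raise ValueError("coefficients must cover exactly the informative symptoms")


@dataclass
class KnowledgeBase:
    """Local snapshot of the term-gene / interaction / pathway resources."""

    symptom_term_map: dict[str, list[str]]
    term_gene_table: dict[str, list[str]]
    interaction_edges: list[tuple[str, str, float]]
    #: pathway name -> (category, member genes); categories are
    #: 'proliferation-type', 'mitochondrial-type' or 'other'
    pathway_sets: dict[str, tuple[str, list[str]]]
    planted_hubs: tuple[str, ...] = ()
    planted_enriched: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for a, b, s in self.interaction_edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            if not 0.0 <= s <= 1.0:
                raise ValueError("interaction scores must be in [0, 1]")
        universe = self.gene_universe
        for name, (_, genes) in self.pathway_sets.items():
            stray = set(genes) - universe
            if stray:
                raise ValueError(f"pathway {name} contains genes outside the universe: {sorted(stray)[:3]}")

    @property
    def gene_universe(self) -> set[str]:
        genes = {g for gs in self.term_gene_table.values() for g in gs}
        genes |= {g for a, b, _ in self.interaction_edges for g in (a, b)}
        return genes


# ---------------------------------------------------------------------------
# expert-score generator
# ---------------------------------------------------------------------------


def _mixture_params(mu: float, kappa: float) -> tuple[float, float]:
    """(binomial p, uniform weight w) so the mixture mean tracks ``mu``.

    The score is binomial(4, p) with probability 1-w and uniform on {0..4}
    with probability w, where w = 1/(1+kappa).  p is solved so the mixture
    mean equals mu and clipped to [0, 1]; near the scale ends a positive w
    makes the exact mean unattainable and the mean saturates toward the
    closest achievable value.
    """
    w = 1.0 / (1.0 + kappa) if math.isfinite(kappa) else 0.0
    if w >= 1.0:
        return 0.5, 1.0
    p = (mu - 2.0 * w) / (4.0 * (1.0 - w))
    return float(np.clip(p, 0.0, 1.0)), w


def generate_expert_scores(
    n_experts: int, items: list[ItemSpec], seed: int, round_id: int = 2
) -> ExpertScoreMatrix:
    """Draw an experts x items Likert score matrix."""
    if n_experts < 2:
        raise ValueError("need at least 2 experts")
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    rng = np.random.default_rng(seed)
    cols = []
    for spec in items:
        p, w = _mixture_params(spec.mu, spec.kappa)
        binom = rng.binomial(4, p, size=n_experts)
        unif = rng.integers(0, 5, size=n_experts)
        use_unif = rng.random(n_experts) < w
        cols.append(np.where(use_unif, unif, binom))
    return ExpertScoreMatrix(
        round_id=round_id,
        item_labels=[s.label for s in items],
        expert_ids=[f"E{i + 1:02d}" for i in range(n_experts)],
        scores=np.column_stack(cols),
    )


def default_expert_items() -> list[ItemSpec]:
    """47 item specs emulating the second survey round.

    Item means come from the packaged reference table; the ten deleted
    items are planted weak (low mean, extra dispersion) so the consensus
    rules have a non-trivial job.
    """
    from .fixtures import load_delphi_items

    table = load_delphi_items()
    specs = []
    for item, row in table.iterrows():
        weak = bool(row["deleted"])
        specs.append(
            ItemSpec(label=str(item), mu=float(row["mean_score"]),
                     kappa=2.0 if weak else math.inf, planted_weak=weak)
        )
    return specs


# ---------------------------------------------------------------------------
# clinical-cohort generator
# ---------------------------------------------------------------------------


def default_truth(symptoms: list[str] | tuple[str, ...] = DEFAULT_SYMPTOMS) -> SyntheticTruth:
    """Planted sparse support: the 19 core symptoms with log-odds 4.0 down to 2.0.

    Effects are positive (each core symptom indicates the syndrome) and
    ordered by the core-symptom importance ranking, so the top-ranked
    symptom carries the largest effect.  The magnitudes are large because
    the reference standard emulated here is a clinician's diagnosis made
    from the same symptom list: the label is close to a deterministic
    function of the informative symptoms (intrinsic AUC ~0.98), as in the
    clinical study this generator stands in for.  Symptoms outside the
    core list are pure noise.  The intercept stored here is a placeholder;
    the cohort generator recalibrates it against the prevalence target.
    """
    informative = tuple(s for s in CORE_SYMPTOMS if s in symptoms)
    if not informative:
        raise ValueError("symptom list shares no symptom with the core set")
    magnitudes = np.linspace(4.0, 2.0, len(informative))
    coefficients = {s: float(m) for s, m in zip(informative, magnitudes)}
    return SyntheticTruth(
        informative_symptoms=informative,
        coefficients=coefficients,
        intercept=0.0,
        age_effect=_AGE_EFFECT,
    )


def _symptom_prevalences(symptoms: list[str]) -> np.ndarray:
    """Deterministic per-symptom marginal frequencies in [0.2, 0.6]."""
    p = len(symptoms)
    return np.linspace(0.6, 0.2, p)


def generate_clinical_cohort(
    n: int = DEFAULT_N,
    symptom_list: list[str] | tuple[str, ...] = DEFAULT_SYMPTOMS,
    truth: SyntheticTruth | None = None,
    prevalence_target: float = DEFAULT_PREVALENCE,
    seed: int = 0,
) -> tuple[ClinicalDataset, SyntheticTruth]:
    """Simulate a cross-sectional cohort under a sparse logistic model.

    Symptom indicators are independent Bernoulli draws given age (the
    younger group carries a slightly higher symptom burden); the diagnosis
    is Bernoulli with log-odds ``intercept + sum(coef * symptom) +
    age_effect * 1[age 3-6]``.  The intercept is calibrated by
    root-finding on the realized covariates so the expected prevalence
    equals ``prevalence_target`` (the empirical prevalence then varies
    within binomial error).  The younger age group is enriched among
    positives through both the direct age effect and the higher symptom
    burden, mirroring the reference cohort's age pattern.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not symptom_list:
        raise ValueError("symptom list must be nonempty")
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError("prevalence_target must be in (0, 1)")
    symptom_list = list(symptom_list)
    if truth is None:
        truth = default_truth(symptom_list)
    unknown = set(truth.informative_symptoms) - set(symptom_list)
    if unknown:
        raise ValueError(f"truth references unknown symptoms: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    age_young = (rng.random(n) < _P_AGE_YOUNG).astype(int)
    gender = np.where(rng.random(n) < _P_MALE, "male", "female")
    # symptom burden is slightly higher in the younger group (and lower in
    # the older one, keeping the marginal prevalence fixed)
    f_young = 1.0 + _AGE_PREV_DELTA
    f_old = 1.0 - _AGE_PREV_DELTA * _P_AGE_YOUNG / (1.0 - _P_AGE_YOUNG)
    base = _symptom_prevalences(symptom_list)
    per_subject = np.clip(np.where(age_young[:, None] == 1, base * f_young, base * f_old), 0.01, 0.97)
    X = (rng.random((n, len(symptom_list))) < per_subject).astype(int)

    beta = np.array([truth.coefficients.get(s, 0.0) for s in symptom_list])
    eta = X @ beta + truth.age_effect * age_young

    def mean_prev(c: float) -> float:
        return float(expit(eta + c).mean()) - prevalence_target

    intercept = brentq(mean_prev, -60.0, 60.0, xtol=1e-10)
    labels = rng.random(n) < expit(eta + intercept)

    frame = pd.DataFrame(X, columns=symptom_list)
    frame.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(n)])
    frame.insert(1, "gender", gender)
    frame.insert(2, "age_group", np.where(age_young == 1, "3-6", "7-14"))
    frame["label"] = np.where(labels, "positive", "negative")

    calibrated = SyntheticTruth(
        informative_symptoms=truth.informative_symptoms,
        coefficients=dict(truth.coefficients),
        intercept=float(intercept),
        age_effect=truth.age_effect,
    )
    return ClinicalDataset(frame=frame, symptoms=symptom_list), calibrated


# ---------------------------------------------------------------------------
# knowledge-base generator
# ---------------------------------------------------------------------------


def generate_knowledge_base(
    n_genes: int = 300,
    n_terms: int = 20,
    n_pathways: int = 12,
    hub_fraction: float = 0.1,
    seed: int = 0,
    enrichment: float = 4.0,
    symptoms: list[str] | tuple[str, ...] | None = None,
) -> KnowledgeBase:
    """Simulate HPO/STRING/pathway-style snapshots with planted structure.

    * The interaction graph is heavy-tailed: a planted hub set
      (``hub_fraction`` of genes) attaches to ~30% of the universe while
      background genes get ~3 partners, so a median-degree hub filter is
      non-trivial.
    * Half the pathways (category 'proliferation-type') sample members with
      hub genes over-weighted by ``enrichment``; the rest are drawn
      uniformly ('mitochondrial-type' / 'other').
    * The symptom -> term map covers the core symptoms, with the
      tongue/fur/pulse-style symptoms mapping to no term at all.
    """
    if min(n_genes, n_terms, n_pathways) < 1:
        raise ValueError("counts must be at least 1")
    if not 0.0 < hub_fraction < 1.0:
        raise ValueError("hub_fraction must be in (0, 1)")
    if enrichment < 1.0:
        raise ValueError("enrichment factor must be >= 1")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    n_hubs = max(1, int(round(hub_fraction * n_genes)))
    hubs = genes[:n_hubs]
    is_hub = np.zeros(n_genes, dtype=bool)
    is_hub[:n_hubs] = True

    # interaction edges: sparse background + dense hub attachment
    edge_set: set[tuple[int, int]] = set()
    for i in range(n_genes):
        k = max(1, rng.poisson(3))
        for j in rng.integers(0, n_genes, size=k):
            if i != j:
                edge_set.add((min(i, int(j)), max(i, int(j))))
    hub_k = max(4, int(0.3 * n_genes))
    for h in range(n_hubs):
        partners = rng.choice(n_genes, size=min(hub_k, n_genes - 1), replace=False)
        for j in partners:
            if h != j:
                edge_set.add((min(h, int(j)), max(h, int(j))))
    edges_sorted = sorted(edge_set)
    scores = rng.uniform(0.15, 1.0, size=len(edges_sorted))
    interaction_edges = [
        (genes[a], genes[b], round(float(s), 3)) for (a, b), s in zip(edges_sorted, scores)
    ]

    # term annotations: hubs over-weighted threefold so symptom queries reach them
    weights = np.where(is_hub, 3.0, 1.0)
    weights = weights / weights.sum()
    term_gene_table: dict[str, list[str]] = {}
    for t in range(n_terms):
        size = min(n_genes, 5 + rng.poisson(15))
        members = rng.choice(n_genes, size=size, replace=False, p=weights)
        term_gene_table[f"T{t:03d}"] = sorted(genes[i] for i in members)

    # pathway gene sets; first half planted-enriched in hub genes.  The
    # enrichment factor is the expected hub-overlap multiple relative to a
    # uniform draw: the hub share of an enriched set is enrichment * (hub
    # fraction of the universe), capped below certainty
    n_enriched = max(1, n_pathways // 2)
    p_null = n_hubs / n_genes
    p_enr = min(0.9, enrichment * p_null)
    w_hub = p_enr * (n_genes - n_hubs) / max(1e-12, (1.0 - p_enr) * n_hubs)
    enr_weights = np.where(is_hub, w_hub, 1.0)
    enr_weights = enr_weights / enr_weights.sum()
    unif = np.full(n_genes, 1.0 / n_genes)
    pathway_sets: dict[str, tuple[str, list[str]]] = {}
    planted_enriched = []
    for p in range(n_pathways):
        size = min(n_genes, 15 + rng.poisson(15))
        if p < n_enriched:
            category = "proliferation-type"
            members = rng.choice(n_genes, size=size, replace=False, p=enr_weights)
            name = f"P{p:02d}_proliferation"
            planted_enriched.append(name)
        else:
            category = "mitochondrial-type" if p % 2 == 0 else "other"
            members = rng.choice(n_genes, size=size, replace=False, p=unif)
            name = f"P{p:02d}_background"
        pathway_sets[name] = (category, sorted(genes[i] for i in members))

    # symptom -> term map; fur/pulse-style findings have no ontology term
    symptoms = list(symptoms) if symptoms is not None else list(CORE_SYMPTOMS)
    unmappable = {
        "Thick fur", "Yellow fur", "Slippery pulse",
        "Feverish feeling in palms and soles", "Smelly stool", "Belching",
        "Worse after improper diet",
    }
    term_ids = sorted(term_gene_table)
    symptom_term_map: dict[str, list[str]] = {}
    for s in symptoms:
        if s in unmappable:
            symptom_term_map[s] = []
        else:
            k = 1 + int(rng.integers(0, min(3, n_terms)))
            picks = rng.choice(len(term_ids), size=min(k, len(term_ids)), replace=False)
            symptom_term_map[s] = sorted(term_ids[i] for i in picks)
    if all(not v for v in symptom_term_map.values()):
        symptom_term_map[symptoms[0]] = [term_ids[0]]

    return KnowledgeBase(
        symptom_term_map=symptom_term_map,
        term_gene_table=term_gene_table,
        interaction_edges=interaction_edges,
        pathway_sets=pathway_sets,
        planted_hubs=tuple(hubs),
        planted_enriched=tuple(planted_enriched),
    )


# ---------------------------------------------------------------------------
# snapshot I/O (TSV / GMT)
# ---------------------------------------------------------------------------


def write_knowledge_base(kb: KnowledgeBase, directory) -> dict[str, Path]:
    """Write the four snapshot files; output is byte-deterministic."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "term_gene": directory / "term_gene.tsv",
        "interactions": directory / "interactions.tsv",
        "pathways": directory / "pathways.gmt",
        "symptom_terms": directory / "symptom_terms.tsv",
    }
    with open(paths["term_gene"], "w") as fh:
        for term in sorted(kb.term_gene_table):
            for gene in sorted(kb.term_gene_table[term]):
                fh.write(f"{term}\t{gene}\n")
    with open(paths["interactions"], "w") as fh:
        for a, b, s in sorted(kb.interaction_edges):
            fh.write(f"{a}\t{b}\t{s:.3f}\n")
    with open(paths["pathways"], "w") as fh:
        for name in sorted(kb.pathway_sets):
            category, members = kb.pathway_sets[name]
            fh.write(name + "\t" + category + "\t" + "\t".join(sorted(members)) + "\n")
    with open(paths["symptom_terms"], "w") as fh:
        for symptom in kb.symptom_term_map:
            terms = ",".join(kb.symptom_term_map[symptom])
            fh.write(f"{symptom}\t{terms}\n")
    return paths


def read_knowledge_base(directory) -> KnowledgeBase:
    """Read a snapshot directory written by :func:`write_knowledge_base`."""
    directory = Path(directory)
    term_gene: dict[str, list[str]] = {}
    for line in (directory / "term_gene.tsv").read_text().splitlines():
        term, gene = line.split("\t")
        term_gene.setdefault(term, []).append(gene)
    edges = []
    for line in (directory / "interactions.tsv").read_text().splitlines():
        a, b, s = line.split("\t")
        edges.append((a, b, float(s)))
    pathways: dict[str, tuple[str, list[str]]] = {}
    for line in (directory / "pathways.gmt").read_text().splitlines():
        parts = line.split("\t")
        pathways[parts[0]] = (parts[1], parts[2:])
    symptom_terms: dict[str, list[str]] = {}
    for line in (directory / "symptom_terms.tsv").read_text().splitlines():
        parts = line.split("\t")
        symptom_terms[parts[0]] = parts[1].split(",") if len(parts) > 1 and parts[1] else []
    return KnowledgeBase(
        symptom_term_map=symptom_terms,
        term_gene_table=term_gene,
        interaction_edges=edges,
        pathway_sets=pathways,
    )
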