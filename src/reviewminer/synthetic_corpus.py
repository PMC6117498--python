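"""Synthetic labeled review corpora drawn from the labeled-LDA generative
process, with group-dependent label prevalences and optional raw-text noise.

The original review corpus is not publicly deposited, so every downstream
stage is exercised on generated data whose *shape* mirrors the real dataset:
nine disease subcorpora with proportional sizes and mean review lengths scaled
from the published descriptive statistics, multi-label documents whose tokens
are emitted by per-label word distributions, and planted differences in label
prevalence between patient groups (acute vs chronic, mild vs serious).

Generative process per document: fix its group, draw a label set from the
group's per-label prevalences, draw a mixture theta over that label set from
Dir(alpha_true), draw a length, then for each token draw a label from theta
and a word from that label's phi_true row.  This is exactly the model the
labeled-LDA sampler inverts, so parameter recovery is well-posed.

The vocabulary is synthetic ("w0000"...) plus a small reserved inventory of
entity placeholders and, for raw-text rendering, stopword and synonym-variant
tokens; no real Chinese text is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus, Review, load_review_statistics
from .preprocess import PLACEHOLDERS

__all__ = [
    "GeneratorConfig", "GroundTruth", "NoiseModel",
    "sample_phi", "generate_corpus", "render_raw_text",
    "expected_mean_theta", "reference_shape_config", "default_noise_model",
    "DEFAULT_LABELS",
]

DEFAULT_LABELS = ["ME", "MC", "MAP", "CS", "F", "OP", "PP", "S", "DAP"]

#: Placeholders given vocabulary slots in the default preset.
PRESET_ENTITY_TOKENS = ("#BODY_TEMPERATURE#", "#AGE#", "#MONEY#")


@dataclass
class GeneratorConfig:
    """Everything needed to draw a labeled corpus.

    ``label_prevalence`` maps each group to per-label inclusion probabilities;
    ``group_sizes`` fixes the number of documents per group; ``doc_length``
    maps each group to a (mean, dispersion) pair for a negative-binomial
    length (dispersion ``None`` gives Poisson); ``labels_per_doc`` is an
    optional distribution over label-set cardinality — when given, a
    cardinality is drawn first and that many distinct labels are chosen with
    probability proportional to the prevalence weights, otherwise each label
    is an independent Bernoulli(prevalence) draw (empty sets are resampled in
    both schemes).
    """

    L: int
    vocab_size: int
    group_sizes: dict[str, int]
    label_prevalence: dict[str, Sequence[float]]
    beta_true: float = 0.05
    alpha_true: float = 2.0
    doc_length: dict[str, tuple[float, Optional[float]]] = field(
        default_factory=lambda: {})
    default_doc_length: tuple[float, Optional[float]] = (80.0, 10.0)
    labels_per_doc: Optional[dict[int, float]] = None
    label_ids: Optional[list[str]] = None
    vocab: Optional[list[str]] = None
    group_metadata: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < self.L:
            raise ValueError(
                "vocab_size must be >= L (topics otherwise indistinguishable)")
        if self.label_ids is None:
            self.label_ids = (DEFAULT_LABELS if self.L == 9
                              else [f"t{i}" for i in range(self.L)])
        if len(self.label_ids) != self.L:
            raise ValueError("label_ids must have length L")
        for g, sz in self.group_sizes.items():
            if sz < 1:
                raise ValueError(f"group {g!r}: group_sizes must be >= 1")
        for g, prev in self.label_prevalence.items():
            prev = np.asarray(prev, dtype=float)
            if prev.shape != (self.L,):
                raise ValueError(f"group {g!r}: prevalence must have length L")
            if ((prev < 0) | (prev > 1)).any():
                raise ValueError(f"group {g!r}: prevalences must be in [0,1]")
            if prev.sum() == 0:
                raise ValueError(f"group {g!r}: prevalence row is all zero")
        if self.labels_per_doc is not None:
            for c in self.labels_per_doc:
                if not 1 <= c <= self.L:
                    raise ValueError("labels_per_doc support must be within 1..L")
        if self.vocab is not None and len(self.vocab) != self.vocab_size:
            raise ValueError("explicit vocab must have vocab_size entries")

    def vocabulary(self) -> list[str]:
        if self.vocab is not None:
            return list(self.vocab)
        return [f"w{i:04d}" for i in range(self.vocab_size)]


@dataclass
class GroundTruth:
    """The latent quantities a recovery experiment compares against."""

    phi_true: np.ndarray                 # L x vocab_size, row-stochastic
    label_ids: list[str]
    label_sets: list[set[str]] = field(default_factory=list)
    theta_true: Optional[np.ndarray] = None   # M x L, support on label set
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.phi_true.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi_true rows must sum to 1")


def sample_phi(config: GeneratorConfig) -> GroundTruth:
    """Draw the per-label word distributions phi_true ~ Dir(beta_true)."""
    rng = np.random.default_rng(config.seed)
    phi = rng.dirichlet([config.beta_true] * config.vocab_size, size=config.L)
    # guard against exact zeros from extreme concentrations
    phi = np.maximum(phi, 1e-300)
    phi /= phi.sum(axis=1, keepdims=True)
    return GroundTruth(phi_true=phi, label_ids=list(config.label_ids))


def _draw_label_set(rng, prevalence: np.ndarray, labels_per_doc) -> np.ndarray:
    """Indices of the document's labels; never empty."""
    L = prevalence.shape[0]
    if labels_per_doc is None:
        for _ in range(1000):
            picked = rng.random(L) < prevalence
            if picked.any():
                return np.flatnonzero(picked)
        raise RuntimeError("label-set rejection sampling failed to terminate")
    cards = sorted(labels_per_doc)
    probs = np.array([labels_per_doc[c] for c in cards], dtype=float)
    probs /= probs.sum()
    c = int(rng.choice(cards, p=probs))
    weights = prevalence.copy()
    chosen = []
    for _ in range(c):
        w = weights / weights.sum()
        k = int(rng.choice(L, p=w))
        chosen.append(k)
        weights[k] = 0.0
    return np.array(sorted(chosen), dtype=int)


def _draw_length(rng, mean: float, dispersion: Optional[float]) -> int:
    if dispersion is None:
        n = rng.poisson(mean)
    else:
        p = dispersion / (dispersion + mean)
        n = rng.negative_binomial(dispersion, p)
    return max(1, int(n))


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a full labeled corpus plus its ground truth.

    Groups are laid out in ``group_sizes`` order; each review carries the
    group's metadata (disease name, sampled hospital level, doctor id) so all
    grouping schemes apply downstream.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_phi(config)
    vocab = config.vocabulary()
    reviews: list[Review] = []
    label_sets: list[set[str]] = []
    thetas: list[np.ndarray] = []
    groups: list[str] = []
    doc_no = 0
    for group, size in config.group_sizes.items():
        prevalence = np.asarray(config.label_prevalence[group], dtype=float)
        mean_len, disp = config.doc_length.get(group, config.default_doc_length)
        meta = config.group_metadata.get(group, {})
        disease = meta.get("disease", group)
        level_probs = meta.get("hospital_level_probs")
        doctor_pool = meta.get("n_doctors")
        for _ in range(size):
            idx = _draw_label_set(rng, prevalence, config.labels_per_doc)
            theta_sub = rng.dirichlet([config.alpha_true] * len(idx))
            theta = np.zeros(config.L)
            theta[idx] = theta_sub
            n_d = _draw_length(rng, mean_len, disp)
            topics = rng.choice(config.L, size=n_d, p=theta)
            words = np.empty(n_d, dtype=int)
            for k in np.unique(topics):
                sel = topics == k
                words[sel] = rng.choice(
                    config.vocab_size, size=int(sel.sum()), p=truth.phi_true[k])
            hospital = None
            if level_probs:
                levels = sorted(level_probs)
                hospital = str(rng.choice(
                    levels, p=np.array([level_probs[l] for l in levels])))
            doctor = None
            if doctor_pool:
                doctor = f"{group}-dr{int(rng.integers(doctor_pool)):04d}"
            labels = {config.label_ids[i] for i in idx}
            reviews.append(Review(
                doc_id=f"d{doc_no:05d}",
                tokens=[vocab[w] for w in words],
                labels=labels,
                disease=disease,
                hospital_level=hospital,
                doctor_id=doctor,
            ))
            label_sets.append(labels)
            thetas.append(theta)
            groups.append(group)
            doc_no += 1
    truth.label_sets = label_sets
    truth.theta_true = np.vstack(thetas)
    truth.groups = groups
    return Corpus(reviews), truth


def expected_mean_theta(
    config: GeneratorConfig, group: str, n_mc: int = 20000, seed: int = 12345,
) -> np.ndarray:
    """Monte-Carlo expectation of mean theta_true per label for one group.

    Uses E[theta_k | label set] = 1/|set| for k in the set (symmetric
    Dirichlet), so only the label-set distribution needs simulating.
    """
    rng = np.random.default_rng(seed)
    prevalence = np.asarray(config.label_prevalence[group], dtype=float)
    acc = np.zeros(config.L)
    for _ in range(n_mc):
        idx = _draw_label_set(rng, prevalence, config.labels_per_doc)
        acc[idx] += 1.0 / len(idx)
    return acc / n_mc


# ---------------------------------------------------------------------------
# Raw-text rendering (noise injection for round-trip tests)
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Rates and inventories for turning clean tokens into noisy raw text.

    ``entity_rate``: probability that a placeholder token is rendered as a
    concrete surface form ("39°C" for #BODY_TEMPERATURE#); ``synonym_rate``:
    probability that a token with variants is rendered as one of them;
    ``stopword_rate``: probability of inserting a random stopword after each
    token.  The preprocessing pipeline restores the clean sequence exactly.
    """

    entity_rate: float = 0.0
    synonym_rate: float = 0.0
    stopword_rate: float = 0.0
    entity_surfaces: dict[str, list[str]] = field(default_factory=dict)
    synonym_variants: dict[str, list[str]] = field(default_factory=dict)
    stopwords: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("entity_rate", "synonym_rate", "stopword_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")

    def thesaurus_mapping(self) -> dict[str, str]:
        """variant -> canonical pairs needed to undo synonym rendering."""
        return {v: canon for canon, variants in self.synonym_variants.items()
                for v in variants}


def default_noise_model(seed: int = 0) -> NoiseModel:
    """A noise model matched to the default preset's reserved vocabulary."""
    surfaces = {
        "#BODY_TEMPERATURE#": ["36.5°C", "37°C", "38.2°C", "39°C", "40°C"],
        "#AGE#": ["5岁", "63岁", "12-year-old", "7yo"],
        "#MONEY#": ["¥200", "300元", "$45.50", "120yuan"],
    }
    variants = {f"w{i:04d}": [f"w{i:04d}syn"] for i in range(3, 23)}
    stop = ["the", "a", "of", "is", "and", "to", "in", "it", "that", "was"]
    return NoiseModel(entity_rate=1.0, synonym_rate=0.3, stopword_rate=0.2,
                      entity_surfaces=surfaces, synonym_variants=variants,
                      stopwords=stop, seed=seed)


def render_raw_text(corpus: Corpus, noise: NoiseModel) -> Corpus:
    """Render each review's tokens as noisy whitespace-joined raw text.

    The returned reviews carry both the rendered ``raw_text`` and the original
    clean ``tokens`` — the sequence preprocessing is expected to recover.
    Rendering is reproducible under ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    out: list[Review] = []
    for r in corpus:
        if r.tokens is None:
            raise ValueError(f"review {r.doc_id!r} has no tokens to render")
        surface: list[str] = []
        for tok in r.tokens:
            rendered = tok
            if tok in PLACEHOLDERS and tok in noise.entity_surfaces:
                if rng.random() < noise.entity_rate:
                    forms = noise.entity_surfaces[tok]
                    rendered = forms[int(rng.integers(len(forms)))]
            elif tok in noise.synonym_variants:
                if rng.random() < noise.synonym_rate:
                    forms = noise.synonym_variants[tok]
                    rendered = forms[int(rng.integers(len(forms)))]
            surface.append(rendered)
            if noise.stopwords and rng.random() < noise.stopword_rate:
                surface.append(
                    noise.stopwords[int(rng.integers(len(noise.stopwords)))])
        out.append(Review(
            doc_id=r.doc_id, raw_text=" ".join(surface), tokens=list(r.tokens),
            labels=set(r.labels) if r.labels is not None else None,
            disease=r.disease, hospital_level=r.hospital_level,
            doctor_id=r.doctor_id,
        ))
    return Corpus(out)


# ---------------------------------------------------------------------------
# Default preset mirroring the published data shape
# ---------------------------------------------------------------------------

# Per-disease label-inclusion probabilities [ME MC MAP CS F OP PP S DAP].
# Directions mirror the published group contrasts: acute-disease reviews dwell
# on symptoms; chronic ones on communication, financing, diagnosis; the mild
# disease (influenza) on ethics, process, patient profile and symptoms; the
# serious cancers on competence, prescriptions, financing and diagnosis.
_ACUTE = [0.30, 0.30, 0.30, 0.22, 0.18, 0.30, 0.35, 0.70, 0.22]
_MILD = [0.45, 0.30, 0.30, 0.22, 0.18, 0.50, 0.55, 0.75, 0.22]
_CHRONIC = [0.30, 0.30, 0.30, 0.42, 0.48, 0.30, 0.25, 0.25, 0.45]
_SERIOUS = [0.25, 0.60, 0.50, 0.30, 0.45, 0.25, 0.20, 0.25, 0.60]

_PRESET_PREVALENCE = {
    "Influenza": _MILD,
    "Infantile pneumonia": _ACUTE,
    "Infantile diarrhea": _ACUTE,
    "Hyperthyroidism": _ACUTE,
    "Hypertension": _CHRONIC,
    "Diabetes": _CHRONIC,
    "Infertility": _CHRONIC,
    "Liver cancer": _SERIOUS,
    "Gastric cancer": _SERIOUS,
}

_LENGTH_SCALE = 0.2          # desk-scale review lengths
_HOSPITAL_PROBS = {"A": 0.55, "B": 0.30, "C": 0.15}


def reference_shape_config(
    total_docs: int = 3000,
    vocab_size: int = 500,
    seed: int = 7,
    labels_per_doc: Optional[dict[int, float]] = None,
) -> GeneratorConfig:
    """The default emulation preset: nine disease subcorpora with sizes
    proportional to the published review counts (scaled to ``total_docs``),
    mean lengths 0.2x the published per-review word counts, and planted
    group-dependent label prevalences.

    The first three vocabulary slots are reserved entity placeholders so that
    raw-text rendering and entity normalization can be exercised end to end.
    """
    stats = load_review_statistics()
    counts = dict(zip(stats["group"], stats["n_reviews"]))
    lengths = dict(zip(stats["group"], stats["mean_length"]))
    doctors = dict(zip(stats["group"], stats["n_doctors"]))
    total = sum(counts.values())
    sizes = {d: max(1, int(round(total_docs * n / total)))
             for d, n in counts.items()}
    # nudge the largest group so sizes sum exactly to total_docs
    largest = max(sizes, key=sizes.get)
    sizes[largest] += total_docs - sum(sizes.values())

    if labels_per_doc is None:
        labels_per_doc = {1: 0.35, 2: 0.40, 3: 0.25}

    vocab = list(PRESET_ENTITY_TOKENS) + [
        f"w{i:04d}" for i in range(len(PRESET_ENTITY_TOKENS), vocab_size)]
    scale = total_docs / total
    metadata = {
        d: {
            "disease": d,
            "hospital_level_probs": dict(_HOSPITAL_PROBS),
            "n_doctors": max(1, int(round(doctors[d] * scale))),
        }
        for d in sizes
    }
    return GeneratorConfig(
        L=9,
        vocab_size=vocab_size,
        group_sizes=sizes,
        label_prevalence={d: _PRESET_PREVALENCE[d] for d in sizes},
        doc_length={d: (lengths[d] * _LENGTH_SCALE, 10.0) for d in sizes},
        labels_per_doc=labels_per_doc,
        vocab=vocab,
        group_metadata=metadata,
        seed=seed,
    )
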