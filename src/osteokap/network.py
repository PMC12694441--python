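"""Participant compatibility network.

Each participant is discretized into four feature classes —
anthropometric (age band, BMI category, sex), demographic (education
low/high, rural/urban), lifestyle (six yes/no behaviours) and clinical
(five yes/no history items).  Two participants are compatible when they
match enough features inside enough classes: the within-class thresholds
are anthropometric >= 2/3, demographic 2/2, lifestyle >= 5/6 and
clinical >= 4/5, and an edge requires at least three of the four class
criteria to pass.  The two-level rule encodes overall phenotypic
similarity rather than agreement on any single dominant feature.

The published feature list names only five lifestyle behaviours against
a /6 threshold; vitamin D supplementation — the one remaining binary
lifestyle item in the questionnaire — is used as the sixth and can be
reconfigured through the class rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from osteokap.records import ParticipantRecord, DerivedVariables, derive

__all__ = [
    "DiscreteProfile", "ClassRule", "DiscretizationError",
    "FEATURE_CLASSES", "default_class_rules",
    "discretize_profile", "class_match", "are_compatible", "build_graph",
    "write_edge_list", "write_graphml",
]


class DiscretizationError(ValueError):
    """Participant outside the discretization's domain (e.g. age >= 90)."""


AGE_BINS = ("40-49", "50-59", "60-69", "70-79", "80-89")

#: class name -> ordered feature names
FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "anthropometric": ("age_bin", "bmi_bin", "sex"),
    "demographic": ("education_bin", "environment"),
    "lifestyle": ("calcium_supplement", "vitamin_d_supplement", "alcohol_any",
                  "coffee", "smoker", "physically_active"),
    "clinical": ("fracture_history", "comorbidities", "osteoporosis_diagnosis",
                 "dxa_ever", "osteoporosis_treatment"),
}


@dataclass(frozen=True)
class ClassRule:
    """Within-class concordance threshold: pass iff >= min_matches features agree."""
    class_name: str
    feature_names: tuple
    min_matches: int

    def __post_init__(self):
        if not (1 <= self.min_matches <= len(self.feature_names)):
            raise ValueError(
                f"{self.class_name}: min_matches {self.min_matches} outside "
                f"[1, {len(self.feature_names)}]")


def default_class_rules() -> dict[str, ClassRule]:
    """The study's thresholds: anthropometric 2/3, demographic 2/2, lifestyle 5/6, clinical 4/5."""
    mins = {"anthropometric": 2, "demographic": 2, "lifestyle": 5, "clinical": 4}
    return {name: ClassRule(name, FEATURE_CLASSES[name], mins[name])
            for name in FEATURE_CLASSES}


@dataclass(frozen=True)
class DiscreteProfile:
    """The discretized feature vector of one participant, grouped by class."""
    id: str
    anthropometric: tuple      # (age_bin, bmi_bin, sex)
    demographic: tuple         # (education_bin, environment)
    lifestyle: tuple           # 6 booleans
    clinical: tuple            # 5 booleans

    def features(self, class_name: str) -> tuple:
        return getattr(self, class_name)


def age_bin(age_years: int) -> str:
    if not (40 <= age_years <= 89):
        raise DiscretizationError(
            f"age {age_years} outside the 40-89 discretization bands")
    return AGE_BINS[(age_years - 40) // 10]


def discretize_profile(record: ParticipantRecord,
                       derived: DerivedVariables | None = None) -> DiscreteProfile:
    """Map a validated record onto the four-class discrete feature vector.

    Binarizations: alcohol_any is true for occasional or regular drinking;
    physically_active means >= 30 minutes/day; education 'high' means
    college; dxa_ever means at least one scan; osteoporosis_treatment is
    true only for treated, diagnosed participants.
    """
    if derived is None:
        derived = derive(record)
    return DiscreteProfile(
        id=record.id,
        anthropometric=(age_bin(record.age_years), derived.bmi_category, record.sex),
        demographic=("high" if record.education == "college" else "low",
                     record.residency),
        lifestyle=(bool(record.calcium_supplement),
                   bool(record.vitamin_d_supplement),
                   record.alcohol in ("occasional", "regular"),
                   bool(record.caffeine),
                   bool(record.smoker),
                   record.activity in ("m30to60", "gt60")),
        clinical=(bool(record.fracture_history),
                  bool(record.comorbidities),
                  bool(record.osteoporosis_diagnosis),
                  record.dxa_count >= 1,
                  bool(record.on_treatment)),
    )


def class_match(a: DiscreteProfile, b: DiscreteProfile,
                rule: ClassRule) -> tuple[int, bool]:
    """Count identical feature values in one class; pass iff >= min_matches."""
    if rule.class_name not in FEATURE_CLASSES:
        raise KeyError(f"unknown feature class {rule.class_name!r}")
    fa, fb = a.features(rule.class_name), b.features(rule.class_name)
    n_matched = sum(x == y for x, y in zip(fa, fb))
    return n_matched, n_matched >= rule.min_matches


def are_compatible(a: DiscreteProfile, b: DiscreteProfile,
                   rules: Mapping[str, ClassRule] | None = None,
                   min_classes: int = 3) -> bool:
    """Edge criterion: at least ``min_classes`` of the four class rules pass."""
    if rules is None:
        rules = default_class_rules()
    passed = sum(class_match(a, b, rule)[1] for rule in rules.values())
    return passed >= min_classes


def _profile_matrix(profiles: Sequence[DiscreteProfile]) -> np.ndarray:
    """Encode all profile features as one integer matrix for vectorized matching."""
    rows = []
    for p in profiles:
        feats = []
        for cname in FEATURE_CLASSES:
            feats.extend(p.features(cname))
        rows.append(feats)
    cols = list(zip(*rows))
    enc = np.empty((len(profiles), len(cols)), dtype=np.int64)
    for j, col in enumerate(cols):
        levels = {v: i for i, v in enumerate(dict.fromkeys(col))}
        enc[:, j] = [levels[v] for v in col]
    return enc


def build_graph(profiles: Sequence[DiscreteProfile],
                rules: Mapping[str, ClassRule] | None = None,
                min_classes: int = 3) -> nx.Graph:
    """Undirected compatibility graph over all profile pairs.

    Node set equals the profile set (isolates retained; community
    analysis excludes them later).  The pairwise match counts are
    evaluated with vectorized integer comparisons; the result is
    identical to the naive double loop over :func:`are_compatible`.
    """
    if rules is None:
        rules = default_class_rules()
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate profile ids: {dupes}")
    G = nx.Graph()
    G.add_nodes_from(ids)
    if len(profiles) < 2:
        return G

    enc = _profile_matrix(profiles)
    # column slices per class, in FEATURE_CLASSES order
    offsets, start = {}, 0
    for cname, feats in FEATURE_CLASSES.items():
        offsets[cname] = slice(start, start + len(feats))
        start += len(feats)
    n = len(profiles)
    classes_passed = np.zeros((n, n), dtype=np.int8)
    for cname, rule in rules.items():
        block = enc[:, offsets[cname]]
        eq = (block[:, None, :] == block[None, :, :]).sum(axis=2)
        classes_passed += eq >= rule.min_matches
    adj = classes_passed >= min_classes
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if adj[i, j]:
            G.add_edge(ids[i], ids[j])
    return G


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Tab-separated two-column edge list (ids), one edge per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{a}\t{b}\n")


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))
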