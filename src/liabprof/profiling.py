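"""Liability profiling: applicability domain, concern binning and
per-group liability scores.

A query compound is scored by every per-target champion model, yielding a
vector of predicted pACTIVITY values. Each prediction is binned into
"concern" (C, predicted pACTIVITY >= 6.5, i.e. more potent than ~316 nM) or
"not concern" (nC). Flags are aggregated over seven mechanistic liability
groups (cardiovascular, CNS, gastrointestinal, endocrine, pulmonary, renal,
immune) via the packaged target-liability mapping, and each group's
liability score is the concern fraction

    Ls_i = C_i / (C_i + nC_i)  in [0, 1].

Prediction reliability is tracked by a similarity applicability domain (AD):
a model's AD is fulfilled when the query's maximum Tanimoto coefficient to
that model's training fingerprints (2048 bits) exceeds 0.7; the overall AD
score is the fraction of models fulfilled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .curation import CurationError, standardize_structure
from .featurization import FeatureBlock, featurize

__all__ = [
    "LIABILITY_GROUPS",
    "LiabilityMapping",
    "load_default_mapping",
    "ADAssessment",
    "LiabilityProfile",
    "assess_ad",
    "classify_concern",
    "liability_scores",
    "profile_compounds",
]

LIABILITY_GROUPS = ("CV", "CNS", "GI", "ED", "PU", "RE", "IM")

DEFAULT_CONCERN_CUTOFF = 6.5  # log units; 10**-6.5 M ~ 316 nM
DEFAULT_AD_THRESHOLD = 0.7


@dataclass(frozen=True)
class LiabilityMapping:
    """Mapping from the 7 liability groups to their member target symbols."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if set(self.groups) != set(LIABILITY_GROUPS):
            raise ValueError(
                f"mapping must define exactly the groups {LIABILITY_GROUPS}"
            )
        for g, targets in self.groups.items():
            if not targets:
                raise ValueError(f"group {g} has no targets")

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for ts in self.groups.values() for t in ts)

    @classmethod
    def from_yaml(cls, path, known_targets=None) -> "LiabilityMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = {g: tuple(ts) for g, ts in raw.items()}
        mapping = cls(groups)
        if known_targets is not None:
            unknown = mapping.targets - set(known_targets)
            if unknown:
                raise ValueError(f"unknown targets in mapping: {sorted(unknown)}")
        return mapping


def load_default_mapping() -> LiabilityMapping:
    """The packaged target-liability reference table."""
    ref = resources.files("liabprof.data") / "liability_mapping.yaml"
    with resources.as_file(ref) as path:
        return LiabilityMapping.from_yaml(path)


@dataclass(frozen=True)
class ADAssessment:
    max_tc: dict[str, float]  # per target
    fulfilled: dict[str, bool]
    overall_score: float  # fraction of models fulfilled


@dataclass
class LiabilityProfile:
    smiles: str
    predictions: dict[str, float]
    flags: dict[str, str]  # target -> "C" | "nC"
    group_counts: dict[str, tuple[int, int]]  # group -> (C_i, nC_i)
    scores: dict[str, float]  # group -> Ls_i
    ad: ADAssessment
    error: str | None = None


def assess_ad(
    query: FeatureBlock | np.ndarray,
    model,
    threshold: float = DEFAULT_AD_THRESHOLD,
) -> tuple[float, bool]:
    """Maximum Tanimoto similarity of a query to a model's training store.

    ``model`` must carry ``fingerprint_store_`` (n_train x 2048 bits).
    Fulfilled iff max Tc strictly exceeds ``threshold``.
    """
    store = getattr(model, "fingerprint_store_", None)
    if store is None or len(store) == 0:
        raise ValueError("model has no training fingerprint store")
    bits = query.similarity_bits if isinstance(query, FeatureBlock) else np.asarray(query)
    bits = bits.astype(np.float64)
    store = np.asarray(store, dtype=np.float64)
    inter = store @ bits
    union = store.sum(axis=1) + bits.sum() - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / union, 1.0)
    max_tc = float(tc.max())
    return max_tc, bool(max_tc > threshold)


def classify_concern(pactivity: float, cutoff: float = DEFAULT_CONCERN_CUTOFF) -> str:
    """Bin a predicted pACTIVITY into "C" (>= cutoff) or "nC"."""
    if not np.isfinite(pactivity):
        raise ValueError("prediction must be finite")
    return "C" if pactivity >= cutoff else "nC"


def two_sigma_cutoff(train_pactivity) -> float:
    """Variable concern threshold: mean + 2 SD of the training responses."""
    y = np.asarray(train_pactivity, dtype=float)
    return float(y.mean() + 2.0 * y.std(ddof=1))


def liability_scores(
    flags: dict[str, str],
    mapping: LiabilityMapping,
    weights: dict[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, tuple[int, int]]]:
    """Per-group liability scores Ls_i = C_i / (C_i + nC_i).

    Every mapped target must carry a flag; a target contributes to each group
    containing it. Optional per-target ``weights`` generalise the score to a
    weighted concern fraction (uniform by default).
    """
    scores: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for group, targets in mapping.groups.items():
        c = nc = 0
        wc = wtot = 0.0
        for t in targets:
            if t not in flags:
                raise KeyError(f"missing concern flag for mapped target {t!r}")
            w = 1.0 if weights is None else float(weights.get(t, 1.0))
            if flags[t] == "C":
                c += 1
                wc += w
            else:
                nc += 1
            wtot += w
        counts[group] = (c, nc)
        scores[group] = wc / wtot if wtot > 0 else 0.0
    return scores, counts


def profile_compounds(
    smiles_list,
    registry: dict[str, object],
    mapping: LiabilityMapping | None = None,
    cutoff: float = DEFAULT_CONCERN_CUTOFF,
    ad_threshold: float = DEFAULT_AD_THRESHOLD,
    weights: dict[str, float] | None = None,
) -> list[LiabilityProfile]:
    """Full liability profile for a batch of query SMILES.

    For each compound: (i) predict pACTIVITY with every model in the
    registry; (ii) bin predictions into C/nC at ``cutoff``; (iii) aggregate
    flags over the liability groups; (iv) compute per-group scores and the
    overall AD score. Invalid SMILES yield a per-compound error entry
    without aborting the batch.
    """
    if not registry:
        raise ValueError("empty model registry")
    mapping = mapping or load_default_mapping()
    out: list[LiabilityProfile] = []
    empty_ad = ADAssessment({}, {}, 0.0)
    for raw in smiles_list:
        try:
            smi = standardize_structure(raw)
            block = featurize(smi)
        except (CurationError, ValueError) as exc:
            out.append(LiabilityProfile(raw, {}, {}, {}, {}, empty_ad, error=str(exc)))
            continue
        x = block.vector.reshape(1, -1)
        predictions = {t: float(m.predict(x)[0]) for t, m in sorted(registry.items())}
        flags = {t: classify_concern(p, cutoff) for t, p in predictions.items()}
        # targets mapped but not modelled cannot be flagged; restrict each
        # group to the modelled targets (every group must keep at least one)
        modelled = set(flags)
        if mapping.targets <= modelled:
            sub = mapping
        else:
            restricted = {
                g: tuple(t for t in ts if t in modelled)
                for g, ts in mapping.groups.items()
            }
            empty = sorted(g for g, ts in restricted.items() if not ts)
            if empty:
                raise ValueError(f"registry models no target of groups {empty}")
            sub = LiabilityMapping(restricted)
        scores, counts = liability_scores(flags, sub, weights)
        tcs, fulf = {}, {}
        for t, m in sorted(registry.items()):
            tcs[t], fulf[t] = assess_ad(block, m, ad_threshold)
        overall = sum(fulf.values()) / len(fulf)
        out.append(
            LiabilityProfile(smi, predictions, flags, counts, scores,
                             ADAssessment(tcs, fulf, overall))
        )
    return out
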