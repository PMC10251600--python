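"""Synthetic structure-activity panels with known ground truth.

Every pipeline stage is testable without downloads: a packaged fragment
grammar (ring cores, linkers, substituents) assembles valid, diverse SMILES;
a configurable structure-activity function generates per-target pACTIVITY
values whose sample statistics match the emulated corpus (mean ~6.6 log
units, SD ~0.6); and an artifact injector re-introduces everything raw
bioactivity tables are dirty with — censored values, non-human species
tags, counter-ions, replicate measurements with jitter, mixed concentration
units and activity types — with bookkeeping so curation round-trips are
exactly checkable.

The generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ActivityRecord, UNIT_FACTORS, normalize_activity, standardize_structure
from .featurization import compute_physchem, similarity_matrix_from_smiles

__all__ = [
    "SARSpec",
    "ArtifactSpec",
    "SARTruth",
    "generate_library",
    "simulate_activities",
    "inject_artifacts",
    "records_to_frame",
]

# ---------------------------------------------------------------------------
# Fragment grammar: templates are Python format strings whose placeholders
# receive a (linker + terminal substituent) branch. Everything assembled from
# this grammar parses and survives standardization.

CORES_1 = (
    "c1ccc({0})cc1",            # benzene
    "c1ccnc({0})c1",            # pyridine
    "c1cnc({0})nc1",            # pyrimidine
    "c1csc({0})c1",             # thiophene
    "c1cc({0})oc1",             # furan
    "c1ccc2[nH]c({0})cc2c1",    # indole
    "c1ccc2nc({0})ccc2c1",      # quinoline
    "c1ccc2[nH]c({0})nc2c1",    # benzimidazole
    "c1ccc2ccc({0})cc2c1",      # naphthalene
    "C1CCN({0})CC1",            # piperidine
    "C1CCN({0})C1",             # pyrrolidine
    "C1COCCN1{0}",              # morpholine
    "C1CCC({0})CC1",            # cyclohexane
    "c1ccc(-c2ccc({0})cc2)cc1", # biphenyl
)

CORES_2 = (
    "c1ccc({0})c({1})c1",       # ortho-disubstituted benzene
    "c1cc({0})cc({1})c1",       # meta-disubstituted benzene
    "c1cc({0})ccc1{1}",         # para-disubstituted benzene
    "C1CN({0})CCN1{1}",         # piperazine
    "O=C({0})c1ccc({1})cc1",    # aryl ketone/amide
    "O=S(=O)({0})c1ccc({1})cc1",# aryl sulfone/sulfonamide
)

LINKERS = ("", "", "C", "CC", "CCC", "OC", "C(=O)", "C(=O)N", "S(=O)(=O)", "N(C)", "CO")

SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)NC",
    "c1ccccc1", "c1ccncc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(OC)cc1",
    "C1CCCCC1", "N1CCOCC1", "N1CCCC1",
)


def _branch(rng) -> str:
    return str(rng.choice(LINKERS)) + str(rng.choice(SUBSTITUENTS))


def generate_library(n: int, seed: int = 0, max_attempts_factor: int = 200) -> list[str]:
    """Assemble ``n`` unique, standardized SMILES from the fragment grammar.

    All outputs parse, survive standardization unchanged (they carry no
    salts or charges) and are unique post-standardization. Deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise RuntimeError("fragment grammar exhausted before reaching n")
        if rng.random() < 0.55:
            smi = str(rng.choice(CORES_1)).format(_branch(rng))
        else:
            smi = str(rng.choice(CORES_2)).format(_branch(rng), _branch(rng))
        if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - grammar is valid
            continue
        canon = standardize_structure(smi)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


@dataclass(frozen=True)
class SARSpec:
    """Ground-truth structure-activity model for the simulator.

    ``form`` selects the generating function: ``linear`` (weighted z-scored
    physicochemical descriptors — exactly recoverable by the MLR baseline),
    ``fingerprint`` (weights on a seeded subset of informative fingerprint
    bits, so tree models and not only MLR have recoverable signal) or
    ``mixed`` (the default study condition: threshold "activity-cliff"
    effects on molecular weight, logP, TPSA and rotatable bonds, plus
    weaker additive descriptor and fingerprint-bit trends — the kind of
    structure on which tree ensembles outperform a linear baseline).
    The signal is scaled so that signal variance + noise variance equals
    ``activity_sd**2``; Gaussian noise of SD ``noise_sd`` is then added, so
    both the residual SD and the total sample SD land on their targets.
    """

    form: str = "mixed"  # 'linear' | 'fingerprint' | 'mixed'
    noise_sd: float = 0.3
    activity_mean: float = 6.6
    activity_sd: float = 0.6
    n_signal_bits: int = 64
    target_perturbation: float = 0.1  # per-target coefficient jitter (relative)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd >= self.activity_sd:
            raise ValueError("noise_sd must be below activity_sd")
        if self.form not in ("linear", "fingerprint", "mixed"):
            raise ValueError(f"unknown SAR form {self.form!r}")


#: Descriptor columns carrying the threshold effects of the ``mixed`` form
#: (MolWt, LogP, TPSA, NumRotatableBonds in the physchem order).
STEP_DESCRIPTORS = (0, 1, 2, 5)
#: Relative SDs of the (step, linear-descriptor, fingerprint) components of
#: the ``mixed`` form before overall standardization.
MIXED_WEIGHTS = (1.0, 0.4, 0.3)


@dataclass
class SARTruth:
    """Generator bookkeeping for recovery tests."""

    spec: SARSpec
    physchem_weights: dict[str, np.ndarray] = field(default_factory=dict)
    bit_indices: np.ndarray | None = None
    bit_weights: dict[str, np.ndarray] = field(default_factory=dict)
    step_thresholds: np.ndarray | None = None
    step_weights: dict[str, np.ndarray] = field(default_factory=dict)
    signals: dict[str, np.ndarray] = field(default_factory=dict)  # noise-free pACTIVITY
    clean: dict[str, pd.DataFrame] = field(default_factory=dict)
    emitted_values: dict[str, dict[str, list[float]]] = field(default_factory=dict)


def _zscore(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (M - M.mean(axis=0)) / sd


def simulate_activities(
    library: list[str],
    spec: SARSpec = SARSpec(),
    targets: list[str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SARTruth]:
    """Simulate clean per-target records for a compound library.

    Returns ``(clean, truth)`` where ``clean`` maps each target label to a
    DataFrame with columns ``smiles`` and ``pACTIVITY`` and ``truth``
    records the generating coefficients per target.
    """
    targets = targets or ["T1"]
    rng = np.random.default_rng(seed)
    n = len(library)
    phys = _zscore(np.vstack([compute_physchem(s) for s in library]))
    truth = SARTruth(spec)

    fp = None
    if spec.form in ("fingerprint", "mixed"):
        fp = similarity_matrix_from_smiles(library).astype(float)
        prevalence = fp.mean(axis=0)
        informative = np.flatnonzero((prevalence >= 0.05) & (prevalence <= 0.95))
        k = min(spec.n_signal_bits, len(informative))
        truth.bit_indices = rng.choice(informative, size=k, replace=False)

    w_phys = rng.normal(size=phys.shape[1])
    w_bits = rng.normal(size=len(truth.bit_indices)) if truth.bit_indices is not None else None
    w_steps = rng.normal(size=len(STEP_DESCRIPTORS))
    if spec.form == "mixed":
        truth.step_thresholds = rng.normal(0.0, 0.5, size=len(STEP_DESCRIPTORS))

    def norm1(v: np.ndarray) -> np.ndarray:
        return _zscore(v[:, None]).ravel()

    clean: dict[str, pd.DataFrame] = {}
    for t in targets:
        wp = w_phys + spec.target_perturbation * rng.normal(size=w_phys.shape)
        if spec.form == "linear":
            f = norm1(phys @ wp)
            truth.physchem_weights[t] = wp
        elif spec.form == "fingerprint":
            wb = w_bits + spec.target_perturbation * rng.normal(size=w_bits.shape)
            f = norm1(fp[:, truth.bit_indices] @ wb)
            truth.bit_weights[t] = wb
        else:  # mixed: cliffs + additive descriptor trend + bit trend
            ws = w_steps + spec.target_perturbation * rng.normal(size=w_steps.shape)
            wb = w_bits + spec.target_perturbation * rng.normal(size=w_bits.shape)
            d = phys[:, list(STEP_DESCRIPTORS)]
            cliffs = (d > truth.step_thresholds).astype(float) @ ws
            a, b, c = MIXED_WEIGHTS
            f = (a * norm1(cliffs)
                 + b * norm1(d @ wp[list(STEP_DESCRIPTORS)])
                 + c * norm1(fp[:, truth.bit_indices] @ wb))
            truth.step_weights[t] = ws
            truth.physchem_weights[t] = wp
            truth.bit_weights[t] = wb
        f = (f - f.mean()) / (f.std() or 1.0)
        signal_sd = float(np.sqrt(max(spec.activity_sd**2 - spec.noise_sd**2, 0.0)))
        signal = spec.activity_mean + signal_sd * f
        y = signal + rng.normal(0.0, spec.noise_sd, size=n)
        truth.signals[t] = signal
        clean[t] = pd.DataFrame({"smiles": library, "pACTIVITY": y})
    truth.clean = clean
    return clean, truth


@dataclass(frozen=True)
class ArtifactSpec:
    """Fractions and mixes of raw-data artifacts to inject.

    All artifact records (censored, non-human, replicates) are appended on
    top of the clean records, so curation should recover the clean compound
    set exactly; salt counter-ions are applied in place, since salt
    stripping restores the parent structure.
    """

    censored_fraction: float = 0.05
    nonhuman_fraction: float = 0.05
    salt_fraction: float = 0.10
    duplicate_fraction: float = 0.10
    duplicate_jitter_sd: float = 0.2
    unit_mix: tuple[tuple[str, float], ...] = (("nM", 0.6), ("uM", 0.3), ("M", 0.1))
    type_mix: tuple[tuple[str, float], ...] = (
        ("IC50", 0.4), ("EC50", 0.15), ("Ki", 0.35), ("Kd", 0.1)
    )

    def __post_init__(self):
        for frac in (
            self.censored_fraction, self.nonhuman_fraction,
            self.salt_fraction, self.duplicate_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("artifact fractions must lie in [0, 1]")


COUNTERIONS = (".[Na+]", ".[Cl-]", ".[K+]", ".[Br-]", ".O")
NONHUMAN_SPECIES = ("rat", "mouse", "canine", "rattus norvegicus")


def _pick(rng, mix: tuple[tuple[str, float], ...]) -> str:
    labels = [m[0] for m in mix]
    probs = np.array([m[1] for m in mix], dtype=float)
    return str(rng.choice(labels, p=probs / probs.sum()))


def _to_record(rng, smiles: str, pact: float, spec: ArtifactSpec,
               species: str = "Homo sapiens", censor: str = "none") -> tuple[ActivityRecord, float]:
    """Emit one raw record at the given pACTIVITY; returns the record and the
    pACTIVITY it normalizes back to (exact under the unit round-trip)."""
    unit = _pick(rng, spec.unit_mix)
    value = 10.0 ** (-pact) / UNIT_FACTORS[unit.lower()]
    rec = ActivityRecord(
        structure=smiles,
        value=value,
        unit=unit,
        activity_type=_pick(rng, spec.type_mix),
        species=species,
        censor=censor,
    )
    return rec, normalize_activity(value, unit)


def inject_artifacts(
    clean: dict[str, pd.DataFrame],
    spec: ArtifactSpec = ArtifactSpec(),
    seed: int = 0,
) -> tuple[dict[str, list[ActivityRecord]], dict[str, dict[str, list[float]]]]:
    """Dirty a clean panel into raw activity records.

    Returns ``(raw, emitted)``: per-target raw record lists, and per-target
    bookkeeping mapping each clean canonical SMILES to the pACTIVITY values
    of its retained (human, uncensored) emitted records — the per-group
    median of these is what curation must reproduce.
    """
    rng = np.random.default_rng(seed)
    raw: dict[str, list[ActivityRecord]] = {}
    emitted: dict[str, dict[str, list[float]]] = {}
    for t, df in clean.items():
        records: list[ActivityRecord] = []
        book: dict[str, list[float]] = {}
        n = len(df)
        smiles = df["smiles"].tolist()
        pact = df["pACTIVITY"].to_numpy()

        salted = set(rng.choice(n, size=int(round(spec.salt_fraction * n)), replace=False))
        for i in range(n):
            structure = smiles[i] + str(rng.choice(COUNTERIONS)) if i in salted else smiles[i]
            rec, p_eff = _to_record(rng, structure, pact[i], spec)
            records.append(rec)
            book.setdefault(smiles[i], []).append(p_eff)

        n_dup = int(round(spec.duplicate_fraction * n))
        for i in rng.choice(n, size=n_dup, replace=False):
            p_jit = pact[i] + rng.normal(0.0, spec.duplicate_jitter_sd)
            rec, p_eff = _to_record(rng, smiles[i], p_jit, spec)
            records.append(rec)
            book[smiles[i]].append(p_eff)

        n_cens = int(round(spec.censored_fraction * n))
        for i in rng.choice(n, size=n_cens, replace=False):
            rec, _ = _to_record(rng, smiles[i], pact[i], spec,
                                censor=str(rng.choice([">", "<"])))
            records.append(rec)

        n_nh = int(round(spec.nonhuman_fraction * n))
        for i in rng.choice(n, size=n_nh, replace=False):
            rec, _ = _to_record(rng, smiles[i], pact[i], spec,
                                species=str(rng.choice(NONHUMAN_SPECIES)))
            records.append(rec)

        order = rng.permutation(len(records))
        raw[t] = [records[i] for i in order]
        emitted[t] = book
    return raw, emitted


def records_to_frame(raw: dict[str, list[ActivityRecord]]) -> pd.DataFrame:
    """Flatten per-target raw records into one delimited-text-ready table."""
    rows = []
    for t, records in raw.items():
        for rec in records:
            rows.append(
                {
                    "target": t,
                    "structure": rec.structure,
                    "value": rec.value,
                    "unit": rec.unit,
                    "activity_type": rec.activity_type,
                    "species": rec.species,
                    "censor": rec.censor,
                }
            )
    return pd.DataFrame(rows)
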