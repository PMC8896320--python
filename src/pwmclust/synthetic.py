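"""Ground-truth-labeled synthetic fixtures: PWM families, DBD snapshots
and motif-planted weighted sequence sets.

Every stage of the pipeline can be exercised without downloading any
motif database.  Families of PWMs are noisy renditions of a consensus:
each column is drawn from a Dirichlet centred on the consensus base
((1 - eps) one-hot + eps uniform, eps = 0.02) whose concentration
parameter controls within-family similarity; optional length jitter
trims or extends flanks with uniform columns, exercising the alignment's
offset search.  Planted outliers have independent random columns.
Generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ensemble import WeightedSequence, WeightedSequenceSet
from .pwm import ALPHABET, PWM, PWMCollection

EPS = 0.02


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic PWM family around a consensus site."""

    consensus: str
    n_members: int = 8
    concentration: float = 50.0
    length_jitter: int = 0
    dbd_label: str = "unknown_dbd"
    name: str = "TF"

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set(ALPHABET):
            raise ValueError("consensus must be a non-empty ACGT string")
        if self.n_members < 1 or self.concentration <= 0:
            raise ValueError("n_members >= 1 and concentration > 0 required")


def _consensus_base_probs(consensus: str) -> np.ndarray:
    m = np.full((len(consensus), 4), EPS / 4)
    for i, ch in enumerate(consensus):
        m[i, ALPHABET.index(ch)] += 1 - EPS
    return m


def _noisy_matrix(base: np.ndarray, concentration: float,
                  rng: np.random.Generator) -> np.ndarray:
    return np.vstack([
        rng.dirichlet(np.maximum(concentration * row, 1e-3))
        for row in base
    ])


def generate_family(spec: FamilySpec, seed: int = 0
                    ) -> tuple[PWMCollection, dict[str, str]]:
    """Noisy renditions of the consensus PWM; returns (PWMs, truth labels).

    Members are named ``<name>_<k>`` so the DBD classifier recovers the
    family's TF symbol from the name.  With concentration -> infinity the
    members converge to the one-hot consensus.
    """
    rng = np.random.default_rng(seed)
    base = _consensus_base_probs(spec.consensus)
    coll = PWMCollection()
    truth: dict[str, str] = {}
    for k in range(1, spec.n_members + 1):
        mat = _noisy_matrix(base, spec.concentration, rng)
        if spec.length_jitter:
            delta = int(rng.integers(-spec.length_jitter,
                                     spec.length_jitter + 1))
            if delta > 0:
                left = int(rng.integers(0, delta + 1))
                pads = (np.full((left, 4), 0.25),
                        mat,
                        np.full((delta - left, 4), 0.25))
                mat = np.vstack(pads)
            elif delta < 0 and mat.shape[0] + delta >= 1:
                left = int(rng.integers(0, -delta + 1))
                mat = mat[left:mat.shape[0] + delta + left]
        name = f"{spec.name}_{k}"
        coll.add(PWM(name, mat))
        truth[name] = spec.name
    return coll, truth


def random_outlier_pwm(name: str, length: int,
                       rng: np.random.Generator) -> PWM:
    """PWM with independent random sharp columns, unrelated to any family."""
    mat = np.vstack([rng.dirichlet([0.5, 0.5, 0.5, 0.5])
                     for _ in range(length)])
    return PWM(name, mat)


def generate_collection(
    specs: Sequence[FamilySpec],
    outliers_per_family: int = 0,
    seed: int = 0,
) -> tuple[PWMCollection, dict[str, str], list[tuple[str, str]]]:
    """Union of families plus planted outliers.

    Returns (collection, truth labels, DBD snapshot rows).  Truth label
    is the family name, or ``outlier`` for planted outliers; the snapshot
    maps each family's TF symbol to its DBD label, so the classifier
    partitions the collection exactly by family (outliers, absent from
    the snapshot, fall into unknown_dbd).
    """
    rng = np.random.default_rng(seed)
    coll = PWMCollection()
    truth: dict[str, str] = {}
    snapshot: list[tuple[str, str]] = []
    for f_idx, spec in enumerate(specs):
        fam, fam_truth = generate_family(spec, seed=int(rng.integers(2**31)))
        for pwm in fam:
            coll.add(pwm)
        truth.update(fam_truth)
        snapshot.append((spec.name, spec.dbd_label))
        for o in range(1, outliers_per_family + 1):
            name = f"OUT{f_idx}X{o}"
            coll.add(random_outlier_pwm(name, len(spec.consensus), rng))
            truth[name] = "outlier"
    return coll, truth, snapshot


def default_family_specs(n_families: int = 6, n_members: int = 8,
                         concentration: float = 50.0,
                         length_jitter: int = 0) -> list[FamilySpec]:
    """Disjoint-consensus families over distinct DBD labels."""
    consensi = ["CACGTGCA", "TGACTCAT", "GGGGAAGG", "AACCAATT",
                "TTGCGCAA", "CCATATGG", "GAGAGAGT", "ACGCGTAC"]
    dbds = ["bHLH", "bZIP", "C2H2_ZF", "homeodomain", "forkhead", "ETS",
            "HMG", "nuclear receptor"]
    if n_families > len(consensi):
        raise ValueError(f"at most {len(consensi)} built-in families")
    return [
        FamilySpec(consensus=consensi[i], n_members=n_members,
                   concentration=concentration, length_jitter=length_jitter,
                   dbd_label=dbds[i], name=f"TF{i + 1}")
        for i in range(n_families)
    ]


def generate_sequences(pwm: PWM, n_seq: int = 200, seq_len: int = 50,
                       plant_prob: float = 0.8, seed: int = 0
                       ) -> tuple[WeightedSequenceSet, list[tuple[str, int]]]:
    """Uniform-background sequences with motif instances planted.

    With probability ``plant_prob`` each sequence receives one sample
    from the PWM at a uniformly random position; weights are log-normal
    (peak-abundance-like).  Returns the set and the (id, position) truth
    list of planted occurrences.
    """
    if seq_len < len(pwm):
        raise ValueError("seq_len must be >= motif length")
    rng = np.random.default_rng(seed)
    records = []
    truth: list[tuple[str, int]] = []
    w = len(pwm)
    for i in range(n_seq):
        seq = list(rng.choice(list(ALPHABET), size=seq_len))
        sid = f"seq{i:04d}"
        if rng.random() < plant_prob:
            pos = int(rng.integers(0, seq_len - w + 1))
            site = [ALPHABET[int(rng.choice(4, p=row))]
                    for row in pwm.matrix]
            seq[pos:pos + w] = site
            truth.append((sid, pos))
        weight = float(rng.lognormal(mean=3.0, sigma=1.0))
        records.append(WeightedSequence(sid, "".join(seq), weight))
    return WeightedSequenceSet(records), truth


def write_snapshot_tsv(snapshot: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_symbol\tdbd_name\n")
        for tf, dbd in snapshot:
            fh.write(f"{tf}\t{dbd}\n")


def write_truth_tsv(truth: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("pwm_name\ttruth_label\n")
        for name, label in truth.items():
            fh.write(f"{name}\t{label}\n")


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions of one item set."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    from collections import Counter
    ab = Counter(zip(labels_a, labels_b))
    a_c = Counter(labels_a)
    b_c = Counter(labels_b)

    def comb2(x: int) -> float:
        return x * (x - 1) / 2.0

    sum_ab = sum(comb2(v) for v in ab.values())
    sum_a = sum(comb2(v) for v in a_c.values())
    sum_b = sum(comb2(v) for v in b_c.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ab - expected) / (max_index - expected)
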