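"""Position-specific scoring matrices, motif scanning and family classification.

The gene family studied here is defined by a C-terminal CCT domain; companion
N-terminal domains (B-box, pseudo-response-regulator, GATA, zinc finger)
define the subfamilies.  A fixed-length ungapped PSSM per domain, scored in
bits against a background residue distribution, stands in for a profile-HMM
scan: it is exact, fast, and sufficient to recover planted motifs.  The
inclusion threshold is calibrated on background-generated decoys so that the
expected number of false hits across the scanned query set is one; hits whose
expected false count at their score exceeds one are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PSSM",
    "DomainHit",
    "Classification",
    "NullCalibration",
    "build_pssm",
    "calibrate_null",
    "scan",
    "classify",
    "pssm_to_tsv",
    "pssm_from_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

FAMILY_LABELS = ("CMF", "CO", "PRR", "GATA", "ZCCT", "BBOX_ONLY", "PRR_ONLY", "NONE")


@dataclass
class PSSM:
    """Ungapped log-odds matrix (bits), residues x columns."""

    label: str
    log_odds: np.ndarray  # shape (20, length)
    background: np.ndarray  # shape (20,), sums to 1

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=0))


@dataclass
class DomainHit:
    label: str
    start: int
    end: int
    bit_score: float
    expect_like: float


@dataclass
class Classification:
    """Family label derived from the domain-overlap rule, plus a flag for
    proteins that retain a companion domain but lost the CCT domain."""

    family: str
    flag: Optional[str] = None


def build_pssm(
    instances: Sequence[str],
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    label: str = "domain",
) -> PSSM:
    """Build a PSSM from ungapped, equal-length aligned peptide instances.

    ``log_odds[r, c] = log2((count[r,c] + pc*bg[r]) / ((n + pc) * bg[r]))``.
    """
    if len(instances) < 2:
        raise ValueError("need >= 2 instances")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("instances must have equal length")
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    counts = np.zeros((20, length))
    for s in instances:
        for c, aa in enumerate(s.upper()):
            i = _AA_INDEX.get(aa)
            if i is None:
                raise ValueError(f"non-standard residue {aa!r} in instance")
            counts[i, c] += 1
    n = len(instances)
    if pseudocount == 0 and (counts == 0).any():
        # log2(0) columns are tolerated only with pseudocounting; clamp.
        with np.errstate(divide="ignore"):
            lo = np.log2(counts / (n * background[:, None]))
        lo[np.isneginf(lo)] = -50.0
    else:
        num = counts + pseudocount * background[:, None]
        den = (n + pseudocount) * background[:, None]
        lo = np.log2(num / den)
    return PSSM(label=label, log_odds=lo, background=background)


def _window_scores(pssm: PSSM, protein: str) -> np.ndarray:
    """Score of every length-L window; non-standard residues contribute 0."""
    L = pssm.length
    n = len(protein)
    if n < L:
        return np.zeros(0)
    # Row 20 of the padded matrix is all-zero and catches X/* etc.
    padded = np.vstack([pssm.log_odds, np.zeros((1, L))])
    idx = np.fromiter(
        (_AA_INDEX.get(aa, 20) for aa in protein.upper()), dtype=np.intp, count=n
    )
    scores = np.zeros(n - L + 1)
    for c in range(L):
        scores += padded[idx[c : n - L + 1 + c], c]
    return scores


@dataclass
class NullCalibration:
    """Empirical null for one PSSM, from Monte-Carlo decoy scanning.

    ``expect_like(s)`` is the expected number of decoy windows scoring >= s,
    rescaled to ``query_windows`` (the size of the real query set); the
    calibrated ``threshold`` is the smallest score at which that expectation
    drops to 1 -- the analogue of excluding hits with E-value > 1.
    """

    label: str
    decoy_scores: np.ndarray  # sorted ascending
    query_windows: int

    @property
    def n_decoy_windows(self) -> int:
        return len(self.decoy_scores)

    def expect_like(self, score: float) -> float:
        n_ge = self.n_decoy_windows - np.searchsorted(
            self.decoy_scores, score, side="left"
        )
        return float(n_ge) / self.n_decoy_windows * self.query_windows

    @property
    def threshold(self) -> float:
        target = self.n_decoy_windows / self.query_windows  # windows with E == 1
        k = int(np.ceil(target))
        if k >= self.n_decoy_windows:
            return float(self.decoy_scores[0])
        # Smallest score with at most k-1 decoy windows at or above it.
        return float(self.decoy_scores[-k]) + 1e-9


def calibrate_null(
    pssm: PSSM,
    decoy_length_total: int = 200_000,
    n_samples: int = 200,
    seed: int = 0,
    query_windows: int = 10_000,
) -> NullCalibration:
    """Monte-Carlo calibration of the score threshold where the expected
    number of false hits over ``query_windows`` scanned windows equals 1."""
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if not np.any(pssm.log_odds):
        raise ValueError("degenerate PSSM: all-zero log-odds")
    rng = np.random.default_rng(seed)
    per_seq = max(pssm.length, decoy_length_total // n_samples)
    scores: List[np.ndarray] = []
    for _ in range(n_samples):
        residues = rng.choice(20, size=per_seq, p=pssm.background)
        decoy = "".join(AMINO_ACIDS[i] for i in residues)
        w = _window_scores(pssm, decoy)
        if w.size:
            scores.append(w)
    all_scores = np.sort(np.concatenate(scores))
    return NullCalibration(pssm.label, all_scores, query_windows)


def scan(
    pssm: PSSM,
    protein: str,
    threshold: Union[float, NullCalibration],
) -> List[DomainHit]:
    """Sliding-window scan; greedy non-overlapping hit selection.

    Windows scoring below the threshold, or whose expected false count under
    the calibrated null exceeds 1, are excluded.  Hits are returned sorted by
    position and never overlap.
    """
    if len(protein) < 1:
        raise ValueError("protein must be non-empty")
    calibration = threshold if isinstance(threshold, NullCalibration) else None
    thr = calibration.threshold if calibration is not None else float(threshold)
    scores = _window_scores(pssm, protein)
    L = pssm.length
    candidates = [
        (float(s), int(p)) for p, s in enumerate(scores) if s >= thr
    ]
    if calibration is not None:
        candidates = [
            (s, p) for s, p in candidates if calibration.expect_like(s) <= 1.0
        ]
    # Best score first; ties broken by leftmost start.
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: List[DomainHit] = []
    for s, p in candidates:
        if any(p < h.end and h.start < p + L for h in taken):
            continue
        expect = calibration.expect_like(s) if calibration is not None else 0.0
        taken.append(DomainHit(pssm.label, p, p + L, s, expect))
    taken.sort(key=lambda h: h.start)
    return taken


def classify(hits: Iterable[DomainHit]) -> Classification:
    """Overlap rule mapping a protein's domain set to its family.

    CCT alone -> CMF; CCT with a companion -> CO (B-box), PRR, GATA or ZCCT
    (zinc finger), with companion precedence PRR > BBOX > ZF > GATA when more
    than one is present.  A companion without CCT is flagged as a potential
    CCT-domain deletion (BBOX_ONLY / PRR_ONLY); no recognizable domain -> NONE.
    """
    labels = {h.label for h in hits}
    if "CCT" in labels:
        if "PRR" in labels:
            return Classification("PRR")
        if "BBOX" in labels:
            return Classification("CO")
        if "ZF" in labels:
            return Classification("ZCCT")
        if "GATA" in labels:
            return Classification("GATA")
        return Classification("CMF")
    if "BBOX" in labels:
        return Classification("BBOX_ONLY", flag="potential CCT deletion")
    if "PRR" in labels:
        return Classification("PRR_ONLY", flag="potential CCT deletion")
    return Classification("NONE")


def pssm_to_tsv(pssm: PSSM) -> str:
    """Serialize as TSV: a one-line header (label, length, background), then
    residue rows by position columns."""
    bg = ",".join(f"{b:.6g}" for b in pssm.background)
    lines = [f"#label={pssm.label}\tlength={pssm.length}\tbackground={bg}"]
    lines.append("residue\t" + "\t".join(str(c) for c in range(pssm.length)))
    for i, aa in enumerate(AMINO_ACIDS):
        row = "\t".join(f"{v:.6f}" for v in pssm.log_odds[i])
        lines.append(f"{aa}\t{row}")
    return "\n".join(lines) + "\n"


def pssm_from_tsv(text: str) -> PSSM:
    lines = [ln for ln in text.strip().splitlines() if ln]
    header = lines[0]
    if not header.startswith("#label="):
        raise ValueError("missing PSSM header")
    fields = dict(part.split("=", 1) for part in header.lstrip("#").split("\t"))
    label = fields["label"]
    background = np.array([float(x) for x in fields["background"].split(",")])
    rows = {}
    for ln in lines[2:]:
        parts = ln.split("\t")
        rows[parts[0]] = [float(x) for x in parts[1:]]
    lo = np.array([rows[aa] for aa in AMINO_ACIDS])
    return PSSM(label=label, log_odds=lo, background=background)
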