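"""Evaluation metrics for designed sequences.

Four quantities summarize design quality against a native reference:
perplexity (exponentiated mean negative log-likelihood of the native
letters), accuracy (argmax identity), recovery (mean per-position
identity of a population of sampled sequences) and the sc score
(secondary-structure self-consistency: Matthews correlation between the
pair set predicted for each sample and the reference pair set, averaged
over samples).

Positions whose reference letter is N are excluded everywhere.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .structures import BasePairSet

__all__ = [
    "perplexity",
    "accuracy",
    "recovery",
    "sc_score",
    "sc_score_detailed",
    "mcc_pairs",
    "DesignOutput",
    "SecondaryStructurePredictor",
    "NussinovPredictor",
    "RNAfoldPredictor",
    "dotbracket_to_pairs",
]

LETTERS = "ACGU"
_IDX = {c: k for k, c in enumerate(LETTERS)}


def _mask(reference: str) -> np.ndarray:
    return np.array([c in _IDX for c in reference], dtype=bool)


def perplexity(probs: np.ndarray, reference: str) -> float:
    """exp of the mean negative log probability of the native letters."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(reference):
        raise ValueError("probability matrix / reference length mismatch")
    keep = _mask(reference)
    if not keep.any():
        raise ValueError("reference has no unmasked positions")
    rows = np.flatnonzero(keep)
    p = probs[rows, [_IDX[reference[i]] for i in rows]]
    if np.any(p <= 0):
        warnings.warn("zero probability at a reference letter; perplexity=inf")
        return float("inf")
    return float(np.exp(-np.mean(np.log(p))))


def accuracy(probs: np.ndarray, reference: str) -> float:
    """Fraction of unmasked positions where argmax matches the native
    letter (argmax ties resolve to the first of A<C<G<U)."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(reference):
        raise ValueError("probability matrix / reference length mismatch")
    keep = _mask(reference)
    rows = np.flatnonzero(keep)
    pred = probs[rows].argmax(axis=1)
    ref = np.array([_IDX[reference[i]] for i in rows])
    return float(np.mean(pred == ref))


def recovery(samples: list[str], reference: str) -> float:
    """Mean per-position identity of sampled sequences to the native one."""
    if not samples:
        raise ValueError("need at least one sample")
    keep = _mask(reference)
    rows = np.flatnonzero(keep)
    vals = []
    for s in samples:
        if len(s) != len(reference):
            raise ValueError("sample / reference length mismatch")
        vals.append(np.mean([s[i] == reference[i] for i in rows]))
    return float(np.mean(vals))


def mcc_pairs(predicted: BasePairSet | set, reference: BasePairSet | set,
              L: int) -> float:
    """Matthews correlation between two base-pair sets over all C(L,2)
    unordered position pairs.  Both sets empty -> 1.0 (perfectly
    self-consistent absence of structure); undefined denominator -> 0.0.
    """
    pred = predicted.pairs if isinstance(predicted, BasePairSet) else set(predicted)
    ref = reference.pairs if isinstance(reference, BasePairSet) else set(reference)
    pred = {(min(i, j), max(i, j)) for i, j in pred}
    ref = {(min(i, j), max(i, j)) for i, j in ref}
    if not pred and not ref:
        return 1.0
    total = L * (L - 1) // 2
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = total - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


class SecondaryStructurePredictor(Protocol):
    """Adapter contract: sequence in, base-pair set out."""

    def fold(self, sequence: str) -> BasePairSet: ...


def sc_score_detailed(samples: list[str], reference_pairs: BasePairSet,
                      predictor: SecondaryStructurePredictor) -> dict:
    """Per-sample MCC against the reference pairs; failed predictions are
    skipped and counted."""
    scores, errors = [], []
    for k, seq in enumerate(samples):
        try:
            pred = predictor.fold(seq)
        except Exception as exc:  # noqa: BLE001 - adapter boundary
            errors.append(f"sample {k}: {exc}")
            continue
        scores.append(mcc_pairs(pred, reference_pairs, len(seq)))
    return {
        "sc_score": float(np.mean(scores)) if scores else float("nan"),
        "n_evaluated": len(scores),
        "n_failed": len(errors),
        "errors": errors,
    }


def sc_score(samples: list[str], reference_pairs: BasePairSet,
             predictor: SecondaryStructurePredictor) -> float:
    return sc_score_detailed(samples, reference_pairs, predictor)["sc_score"]


def dotbracket_to_pairs(db: str) -> BasePairSet:
    """Parse dot-bracket notation (supports ()[]{}<> nesting levels)."""
    openers = {"(": ")", "[": "]", "{": "}", "<": ">"}
    closers = {v: k for k, v in openers.items()}
    stacks: dict[str, list[int]] = {k: [] for k in openers}
    pairs = set()
    for i, ch in enumerate(db):
        if ch in openers:
            stacks[ch].append(i)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise ValueError(f"unbalanced bracket at position {i}")
            pairs.add((stack.pop(), i))
    for k, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {k!r} at position {stack[-1]}")
    return BasePairSet(pairs=pairs)


_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
              ("G", "U"), ("U", "G")}


class NussinovPredictor:
    """Synthetic stand-in folder: maximum base-pair matching (Nussinov
    dynamic program) over Watson-Crick and wobble pairs with a minimum
    hairpin loop of 3.

    This is NOT EternaFold (or any thermodynamic model); it exists so the
    self-consistency machinery can run without external software, and is
    what the test suite uses.
    """

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, sequence: str) -> BasePairSet:
        L = len(sequence)
        dp = np.zeros((L + 1, L + 1), dtype=int)
        for span in range(self.min_loop + 1, L):
            for i in range(L - span):
                j = i + span
                best = dp[i + 1][j]
                for k in range(i + self.min_loop + 1, j + 1):
                    if (sequence[i], sequence[k]) in _CANONICAL:
                        cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0)
                        best = max(best, cand)
                dp[i][j] = best
        pairs: set[tuple[int, int]] = set()
        self._traceback(sequence, dp, 0, L - 1, pairs)
        return BasePairSet(pairs=pairs)

    def _traceback(self, seq, dp, i, j, pairs):
        if j - i <= self.min_loop:
            return
        if dp[i][j] == dp[i + 1][j]:
            self._traceback(seq, dp, i + 1, j, pairs)
            return
        for k in range(i + self.min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _CANONICAL:
                cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0)
                if dp[i][j] == cand:
                    pairs.add((i, k))
                    self._traceback(seq, dp, i + 1, k - 1, pairs)
                    if k < j:
                        self._traceback(seq, dp, k + 1, j, pairs)
                    return
        self._traceback(seq, dp, i + 1, j, pairs)


class RNAfoldPredictor:
    """Adapter around the ViennaRNA ``RNAfold`` executable (MFE fold)."""

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise FileNotFoundError(f"{executable} not on PATH")
        self.executable = executable

    def fold(self, sequence: str) -> BasePairSet:
        proc = subprocess.run(
            [self.executable, "--noPS"], input=sequence + "\n",
            capture_output=True, text=True, check=True,
        )
        for line in proc.stdout.splitlines():
            token = line.split()[0] if line.split() else ""
            if set(token) <= set("().[]{}<>,") and token:
                return dotbracket_to_pairs(token.replace(",", "."))
        raise RuntimeError("could not parse RNAfold output")


@dataclass
class DesignOutput:
    """Bundle of a design run: pooled probabilities, sampled sequences,
    the native reference and the computed metrics (fractions; multiply
    by 100 for table-style percentages)."""

    probabilities: np.ndarray
    samples: list[str]
    reference: str
    metrics: dict[str, float] = field(default_factory=dict)

    def compute_metrics(
        self,
        reference_pairs: BasePairSet | None = None,
        predictor: SecondaryStructurePredictor | None = None,
    ) -> dict[str, float]:
        self.metrics = {
            "perplexity": perplexity(self.probabilities, self.reference),
            "accuracy": accuracy(self.probabilities, self.reference),
            "recovery": recovery(self.samples, self.reference),
        }
        if reference_pairs is not None and predictor is not None:
            self.metrics["sc_score"] = sc_score(
                self.samples, reference_pairs, predictor
            )
        return self.metrics
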