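"""PWM-based MHC class I presentation classifier.

The classifier emulates, at a fraction of the cost, the boolean output of a
reference presentation predictor (such as netMHCpan with a 2% rank cutoff)
pooled over a patient's MHC-I alleles.  One position weight matrix (PWM) is
built per peptide length L in {8, 9, 10}:

* each matrix entry is the log-probability of observing amino acid *a* at
  position *j* among peptides the reference predictor labels presented
  (e.g. if 4.2% of presented 9-mers carry leucine at position four, the
  leucine/position-four entry of the 9-mer matrix is ``log 0.042``);
* a peptide is scored by summing its per-position entries;
* the decision threshold per length is calibrated so that the PWM flags the
  same number of peptides as presented on a large random calibration set as
  the reference predictor does (e.g. if the reference flags 19.6% of random
  9-mers, the threshold is the 19.6% score quantile).

Peptides containing the unknown residue ``X`` are excluded from training and
receive an "unclear" call at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, Union, runtime_checkable

import numpy as np
import pandas as pd

from .alphabet import (
    AA_INDEX,
    AA_ORDER,
    PEPTIDE_LENGTHS,
    UNCLEAR,
    UNKNOWN,
    validate_peptide,
)

__all__ = [
    "PresentationCall",
    "PresentationPredictor",
    "UnclearPeptideError",
    "NotCalibratedError",
    "sample_random_peptides",
    "LabeledPeptideSet",
    "PWMClassifier",
    "build_pwm",
    "score_peptide",
    "calibrate_threshold",
    "predict_presented",
]

#: A presentation call: True / False, or the UNCLEAR sentinel.
PresentationCall = Union[bool, type(UNCLEAR)]


class UnclearPeptideError(ValueError):
    """Raised when a numeric score is requested for an 'X'-containing peptide."""


class NotCalibratedError(RuntimeError):
    """Raised when boolean predictions are requested before calibration."""


@runtime_checkable
class PresentationPredictor(Protocol):
    """Deterministic peptide -> presented? interface.

    Implementations: :class:`PWMClassifier`, the synthetic
    :class:`~deimmune.synthetic.MotifOracle`, and the optional external
    :class:`~deimmune.netmhcpan.NetMHCpanPredictor`.  Peptides containing
    ``X`` yield :data:`~deimmune.alphabet.UNCLEAR`.
    """

    name: str

    def __call__(self, peptide: str) -> PresentationCall: ...


def sample_random_peptides(
    n: int,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample *n* random peptides, i.i.d. uniform residues and lengths.

    Lengths are drawn uniformly from *lengths*; residues uniformly from the
    20 canonical amino acids.  Reproducible given *seed* (or an explicit
    *rng*).
    """
    lengths = sorted(set(int(L) for L in lengths))
    if not lengths:
        raise ValueError("lengths must be a nonempty set of peptide lengths")
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return []
    aa = np.frombuffer(AA_ORDER.encode(), dtype="S1").astype("U1")
    which = rng.integers(0, len(lengths), size=n)
    peptides: list[str] = []
    for i, L in enumerate(lengths):
        count = int(np.sum(which == i))
        if count == 0:
            continue
        chars = aa[rng.integers(0, 20, size=(count, L))]
        peptides.extend("".join(row) for row in chars)
    # Restore a uniformly shuffled interleaving of lengths.
    order = rng.permutation(n)
    return [peptides[i] for i in order]


@dataclass
class LabeledPeptideSet:
    """Peptides with boolean presentation labels from a reference predictor."""

    peptides: list[str]
    presented: np.ndarray
    source: str = "unknown"
    alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.presented = np.asarray(self.presented, dtype=bool)
        if len(self.peptides) != len(self.presented):
            raise ValueError("peptides and presented labels differ in length")
        for p in self.peptides:
            validate_peptide(p)

    def __len__(self) -> int:
        return len(self.peptides)

    def presented_fraction(self, length: int | None = None) -> float:
        """Fraction labeled presented, overall or restricted to one length."""
        if length is None:
            mask = np.ones(len(self), dtype=bool)
        else:
            mask = np.array([len(p) == length for p in self.peptides])
        if not mask.any():
            raise ValueError(f"no peptides of length {length}")
        return float(self.presented[mask].mean())

    def lengths(self) -> list[int]:
        return sorted({len(p) for p in self.peptides})

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "LabeledPeptideSet":
        """Read a ``peptide,presented`` CSV (presented coded 0/1)."""
        df = pd.read_csv(path)
        return cls(
            peptides=df["peptide"].astype(str).tolist(),
            presented=df["presented"].astype(int).to_numpy().astype(bool),
            source=source or str(path),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"peptide": self.peptides, "presented": self.presented.astype(int)}
        ).to_csv(path, index=False)


def _peptide_matrix(peptides: Sequence[str], length: int) -> np.ndarray:
    """Integer-encode same-length peptides into an (n, L) index matrix."""
    flat = "".join(peptides)
    idx = np.array([AA_INDEX[c] for c in flat], dtype=np.int64)
    return idx.reshape(len(peptides), length)


@dataclass
class PWMClassifier:
    """Per-length log-probability matrices with calibrated score thresholds.

    Attributes
    ----------
    log_probs
        Mapping length -> (20, L) array; rows follow
        :data:`~deimmune.alphabet.AA_ORDER`.
    thresholds
        Mapping length -> calibrated score threshold (``score >= threshold``
        counts as presented).  Empty until :meth:`calibrate` runs.
    reference_fractions
        Mapping length -> fraction of the calibration set the reference
        predictor labeled presented.
    pseudocount
        Count added per amino acid before taking logs (avoids -inf entries).
    calibration_info
        Per length: target presented count, achieved count (ties at the
        boundary score may overshoot), number of boundary ties.
    """

    log_probs: dict[int, np.ndarray]
    pseudocount: float = 0.5
    thresholds: dict[int, float] = field(default_factory=dict)
    reference_fractions: dict[int, float] = field(default_factory=dict)
    calibration_info: dict[int, dict] = field(default_factory=dict)
    source: str = "pwm"

    name: str = field(default="pwm", repr=False)

    # ------------------------------------------------------------------ fit
    @classmethod
    def fit(
        cls,
        labeled: LabeledPeptideSet,
        pseudocount: float = 0.5,
        lengths: Iterable[int] | None = None,
    ) -> "PWMClassifier":
        """Estimate per-length PWMs from the presented peptides of *labeled*.

        Entry (a, j, L) is ``log[(count(a at j) + c) / (n_L + 20 c)]`` where
        the counts run over presented L-mers without ``X`` and *c* is the
        pseudocount.  Raises if a requested length has no presented peptide.
        """
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if lengths is None:
            lengths = labeled.lengths()
        lengths = sorted(set(int(L) for L in lengths))
        log_probs: dict[int, np.ndarray] = {}
        for L in lengths:
            keep = [
                p
                for p, pres in zip(labeled.peptides, labeled.presented)
                if pres and len(p) == L and UNKNOWN not in p
            ]
            if not keep:
                raise ValueError(
                    f"no presented peptides of length {L} to build a PWM from"
                )
            idx = _peptide_matrix(keep, L)
            counts = np.zeros((20, L), dtype=float)
            for j in range(L):
                counts[:, j] = np.bincount(idx[:, j], minlength=20)
            with np.errstate(divide="ignore"):
                log_probs[L] = np.log(
                    (counts + pseudocount) / (len(keep) + 20.0 * pseudocount)
                )
        return cls(log_probs=log_probs, pseudocount=float(pseudocount),
                   source=f"pwm(fit on {labeled.source})")

    # ---------------------------------------------------------------- score
    def score(self, peptide: str) -> float:
        """Sum of per-position log-probabilities for *peptide*."""
        validate_peptide(peptide, tuple(self.log_probs))
        if UNKNOWN in peptide:
            raise UnclearPeptideError(
                f"peptide {peptide!r} contains 'X'; its score is undefined"
            )
        L = len(peptide)
        if L not in self.log_probs:
            raise ValueError(f"no PWM for peptide length {L}")
        m = self.log_probs[L]
        return float(sum(m[AA_INDEX[c], j] for j, c in enumerate(peptide)))

    def score_many(self, peptides: Sequence[str]) -> np.ndarray:
        """Vectorized :meth:`score` over same-or-mixed-length peptides."""
        out = np.empty(len(peptides), dtype=float)
        by_length: dict[int, list[int]] = {}
        for i, p in enumerate(peptides):
            by_length.setdefault(len(p), []).append(i)
        for L, rows in by_length.items():
            if L not in self.log_probs:
                raise ValueError(f"no PWM for peptide length {L}")
            idx = _peptide_matrix([peptides[i] for i in rows], L)
            m = self.log_probs[L]
            out[rows] = m[idx, np.arange(L)].sum(axis=1)
        return out

    # ------------------------------------------------------------ calibrate
    def calibrate(self, calibration: LabeledPeptideSet) -> "PWMClassifier":
        """Set per-length thresholds reproducing the reference presented count.

        For each length L the threshold is the k-th highest calibration score
        with ``k = round(f_L * n_L)``, where ``f_L`` is the fraction the
        reference predictor labeled presented.  Scores tied with the boundary
        are all admitted (the achieved count may overshoot; recorded in
        :attr:`calibration_info`).  Returns ``self`` for chaining.
        """
        for L in sorted(self.log_probs):
            peptides = [
                p for p in calibration.peptides if len(p) == L and UNKNOWN not in p
            ]
            labels = np.array(
                [
                    pres
                    for p, pres in zip(calibration.peptides, calibration.presented)
                    if len(p) == L and UNKNOWN not in p
                ],
                dtype=bool,
            )
            if not peptides:
                raise ValueError(f"calibration set has no peptides of length {L}")
            scores = self.score_many(peptides)
            n = len(scores)
            f = float(labels.mean())
            target = int(round(f * n))
            if target == 0:
                threshold = float(np.max(scores)) + 1.0
                warnings.warn(
                    f"length {L}: reference presented fraction is "
                    f"{f:.4g}; threshold set above the maximum score",
                    stacklevel=2,
                )
                achieved = 0
                ties = 0
            else:
                threshold = float(np.partition(scores, n - target)[n - target])
                achieved = int(np.sum(scores >= threshold))
                ties = int(np.sum(scores == threshold))
            self.thresholds[L] = threshold
            self.reference_fractions[L] = f
            self.calibration_info[L] = {
                "n": n,
                "target_count": target,
                "achieved_count": achieved,
                "boundary_ties": ties,
            }
        return self

    @property
    def is_calibrated(self) -> bool:
        return set(self.thresholds) == set(self.log_probs) and bool(self.log_probs)

    # -------------------------------------------------------------- predict
    def predict(self, peptide: str) -> PresentationCall:
        """True iff ``score(peptide) >= threshold``; ``X`` yields UNCLEAR."""
        if not self.is_calibrated:
            raise NotCalibratedError(
                "PWMClassifier must be calibrated before predicting; "
                "call .calibrate(calibration_set)"
            )
        validate_peptide(peptide, tuple(self.log_probs))
        if UNKNOWN in peptide:
            return UNCLEAR
        return bool(self.score(peptide) >= self.thresholds[len(peptide)])

    __call__ = predict

    def predict_many(self, peptides: Sequence[str]) -> list[PresentationCall]:
        return [self.predict(p) for p in peptides]

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "format": "deimmune-pwm-v1",
            "alphabet": AA_ORDER,
            "pseudocount": self.pseudocount,
            "source": self.source,
            "lengths": {
                str(L): {
                    "log_probs": self.log_probs[L].tolist(),
                    "threshold": self.thresholds.get(L),
                    "reference_fraction": self.reference_fractions.get(L),
                    "calibration": self.calibration_info.get(L),
                }
                for L in sorted(self.log_probs)
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "PWMClassifier":
        if d.get("alphabet", AA_ORDER) != AA_ORDER:
            raise ValueError("PWM file uses an unexpected amino-acid row order")
        obj = cls(
            log_probs={
                int(L): np.asarray(v["log_probs"], dtype=float)
                for L, v in d["lengths"].items()
            },
            pseudocount=float(d.get("pseudocount", 0.5)),
            source=d.get("source", "pwm"),
        )
        for L, v in d["lengths"].items():
            if v.get("threshold") is not None:
                obj.thresholds[int(L)] = float(v["threshold"])
                obj.reference_fractions[int(L)] = float(v["reference_fraction"])
                obj.calibration_info[int(L)] = v.get("calibration") or {}
        return obj

    @classmethod
    def from_json(cls, path: str | Path) -> "PWMClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Functional aliases for the operation-style surface. -----------------------

def build_pwm(
    labeled: LabeledPeptideSet,
    pseudocount: float = 0.5,
    lengths: Iterable[int] | None = None,
) -> PWMClassifier:
    """Build an uncalibrated :class:`PWMClassifier` from labeled peptides."""
    return PWMClassifier.fit(labeled, pseudocount=pseudocount, lengths=lengths)


def score_peptide(pwm: PWMClassifier, peptide: str) -> float:
    """Score *peptide* under *pwm* (sum of log-probability entries)."""
    return pwm.score(peptide)


def calibrate_threshold(
    pwm: PWMClassifier, calibration: LabeledPeptideSet
) -> PWMClassifier:
    """Calibrate per-length thresholds of *pwm* on *calibration* (in place)."""
    return pwm.calibrate(calibration)


def predict_presented(pwm: PWMClassifier, peptide: str) -> PresentationCall:
    """Boolean presentation call for *peptide*; UNCLEAR if it contains 'X'."""
    return pwm.predict(peptide)
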