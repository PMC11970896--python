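"""Design generation, selection, and trade-off evaluation.

The design protocol for a template backbone: sample candidate sequences at
low temperature (default 3 candidates at T=0.1), drop candidates using fewer
than 10 distinct amino-acid types (a degenerate, near-constant chain cannot
fold), predict a structure for each survivor, and pick the final design by

* the minimum-visibility candidate among those with TM-score > 0.9, if any;
* otherwise the maximum-TM-score candidate.

A failed structure prediction is assigned TM-score 0 (0 is reserved for that
case: an unavailable scoring backend raises instead of silently returning 0).

Evaluation metrics: absolute/relative immune-visibility, sequence recovery
against the native template sequence, and TM-score between predicted and
template backbones.  Structure prediction is a pluggable backend; the desk
default perturbs the template with seeded Gaussian noise so the TM gate and
failure paths are exercisable without a folding pipeline.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .presentation import PresentationPredictor
from .sequence_model import InverseFoldingModel
from .structure import BackboneStructure
from .visibility import absolute_visibility, relative_visibility

__all__ = [
    "DesignCandidate",
    "TradeoffRecord",
    "StructurePredictionBackend",
    "GaussianPerturbationBackend",
    "generate_candidates",
    "filter_low_diversity",
    "select_design",
    "sequence_recovery",
    "tm_score",
    "tm_score_builtin",
    "parse_tmalign_output",
    "tmalign_tm_score",
    "evaluate_checkpoint",
    "rank_category_histogram",
    "RANK_BINS",
    "plot_tradeoff",
]


@dataclass
class DesignCandidate:
    """One sampled design and the statistics the selection rule needs."""

    sequence: str
    visibility: int
    distinct_aa_count: int = field(init=False)
    tm_score: float | None = None
    predicted_structure: BackboneStructure | None = None
    log_prob: float | None = None

    def __post_init__(self) -> None:
        self.distinct_aa_count = len(set(self.sequence))


class StructurePredictionBackend(Protocol):
    """Sequence + template -> predicted backbone, or None on failure."""

    def predict(
        self, sequence: str, template: BackboneStructure
    ) -> BackboneStructure | None: ...


class GaussianPerturbationBackend:
    """Desk-scale structure-prediction stand-in.

    Returns the template backbone perturbed with seeded Gaussian coordinate
    noise of scale ``sigma`` (Å); with probability ``fail_probability`` the
    prediction "fails" and returns ``None``, exercising the TM=0 path.
    """

    def __init__(
        self, sigma: float = 0.3, fail_probability: float = 0.0, seed: int = 0
    ) -> None:
        self.sigma = float(sigma)
        self.fail_probability = float(fail_probability)
        self._rng = np.random.default_rng(seed)

    def predict(
        self, sequence: str, template: BackboneStructure
    ) -> BackboneStructure | None:
        if len(sequence) != len(template):
            raise ValueError("sequence length must match the template backbone")
        if self.fail_probability and self._rng.random() < self.fail_probability:
            return None
        coords = template.coords + self._rng.normal(0, self.sigma, template.coords.shape)
        return BackboneStructure(
            coords=coords,
            chain_ids=template.chain_ids.copy(),
            residue_indices=template.residue_indices.copy(),
            sequence=sequence,
            name=f"{template.name}-predicted",
        )


def generate_candidates(
    model: InverseFoldingModel,
    structure: BackboneStructure,
    predictor: PresentationPredictor,
    n: int = 3,
    temperature: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[DesignCandidate]:
    """Sample *n* candidate designs and score their visibility."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    enc = model.encode_backbone(structure)
    out = []
    for _ in range(n):
        s = model.sample_sequence(enc, temperature=temperature, rng=rng)
        vis = absolute_visibility(s.sequence, predictor).absolute_visibility
        out.append(
            DesignCandidate(sequence=s.sequence, visibility=vis, log_prob=s.log_prob)
        )
    return out


def filter_low_diversity(
    candidates: Sequence[DesignCandidate], min_distinct: int = 10
) -> list[DesignCandidate]:
    """Drop candidates with fewer than *min_distinct* amino-acid types."""
    return [c for c in candidates if c.distinct_aa_count >= min_distinct]


def select_design(
    candidates: Sequence[DesignCandidate], tm_threshold: float = 0.9
) -> DesignCandidate | None:
    """Final-design selection rule.

    Among candidates with TM-score strictly above *tm_threshold*, pick the
    one with minimum visibility; if none qualify, pick the maximum-TM-score
    candidate.  Empty input returns ``None``.  Candidates must have a
    TM-score assigned (0 for failed structure predictions).
    """
    cands = list(candidates)
    if not cands:
        return None
    for c in cands:
        if c.tm_score is None:
            raise ValueError("all candidates need a tm_score before selection")
    eligible = [c for c in cands if c.tm_score > tm_threshold]
    if eligible:
        return min(eligible, key=lambda c: c.visibility)
    return max(cands, key=lambda c: c.tm_score)


def sequence_recovery(design: str, template: str) -> float:
    """Fraction of positions where design and template agree."""
    if len(design) != len(template):
        raise ValueError("sequences must have equal length")
    if not design:
        raise ValueError("sequences must be nonempty")
    return sum(a == b for a, b in zip(design, template)) / len(design)


# --------------------------------------------------------------- TM-score
def _tm_d0(n: int) -> float:
    if n > 21:
        return max(0.5, 1.24 * (n - 15) ** (1.0 / 3.0) - 1.8)
    return 0.5


def tm_score_builtin(
    structure_a: BackboneStructure | np.ndarray,
    structure_b: BackboneStructure | np.ndarray,
    max_iter: int = 20,
) -> float:
    """TM-score for same-length structures under positional correspondence.

    Superimposes the CA traces with iterative Kabsch refinement (re-fitting
    on the well-aligned subset until it stabilizes) and evaluates the
    standard TM sum normalized by the template (first-argument) length.
    No alignment search is performed — appropriate for fixed-backbone design
    where residue i corresponds to residue i.
    """
    ca_a = structure_a.ca if isinstance(structure_a, BackboneStructure) else np.asarray(structure_a)
    ca_b = structure_b.ca if isinstance(structure_b, BackboneStructure) else np.asarray(structure_b)
    if ca_a.shape != ca_b.shape:
        raise ValueError("built-in TM-score requires equal-length structures")
    n = len(ca_a)
    if n < 3:
        raise ValueError("need at least 3 residues")
    d0 = _tm_d0(n)
    subset = np.ones(n, dtype=bool)
    best = 0.0
    cutoff = max(d0, 4.5)
    for _ in range(max_iter):
        a_sub, b_sub = ca_a[subset], ca_b[subset]
        mu_a, mu_b = a_sub.mean(0), b_sub.mean(0)
        rot, _rssd = Rotation.align_vectors(a_sub - mu_a, b_sub - mu_b)
        b_fit = rot.apply(ca_b - mu_b) + mu_a
        d = np.linalg.norm(ca_a - b_fit, axis=1)
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        best = max(best, score)
        new_subset = d < cutoff
        if new_subset.sum() < 3:
            break
        if np.array_equal(new_subset, subset):
            break
        subset = new_subset
    return best


def parse_tmalign_output(text: str) -> float:
    """Extract the TM-score normalized by the first (reference) chain."""
    chosen = None
    for line in text.splitlines():
        if line.startswith("TM-score=") and "Chain_1" in line:
            chosen = float(line.split("=")[1].split()[0])
        elif line.startswith("TM-score=") and chosen is None:
            chosen = float(line.split("=")[1].split()[0])
    if chosen is None:
        raise ValueError("no TM-score line found in TMalign output")
    return chosen


def tmalign_tm_score(
    pdb_a: str, pdb_b: str, executable: str = "TMalign"
) -> float:
    """TM-score via the external TMalign program (reference = first file)."""
    exe = shutil.which(executable)
    if exe is None:
        raise RuntimeError(
            f"TMalign executable {executable!r} not found on PATH; "
            "use the built-in backend for same-length structures"
        )
    proc = subprocess.run(
        [exe, pdb_a, pdb_b], capture_output=True, text=True, check=True
    )
    return parse_tmalign_output(proc.stdout)


def tm_score(structure_a, structure_b, backend: str = "builtin") -> float:
    """Structural similarity in (0, 1]; >0.5 same fold, <0.2 unrelated."""
    if backend == "builtin":
        return tm_score_builtin(structure_a, structure_b)
    if backend == "tmalign":
        return tmalign_tm_score(structure_a, structure_b)
    raise ValueError(f"unknown TM-score backend {backend!r}")


# ----------------------------------------------------------- evaluation
@dataclass
class TradeoffRecord:
    """Checkpoint-level means over an evaluation set, plus per-structure rows."""

    checkpoint_id: str
    n_structures: int
    mean_relative_visibility: float
    mean_visibility: float
    mean_sequence_recovery: float
    mean_tm_score: float | None
    per_structure: pd.DataFrame
    hyperparams: dict = field(default_factory=dict)

    def summary(self) -> str:
        tm = "n/a" if self.mean_tm_score is None else f"{self.mean_tm_score:.3f}"
        return (
            f"checkpoint {self.checkpoint_id}: n={self.n_structures}, "
            f"mean relative visibility={self.mean_relative_visibility:.3f}, "
            f"mean visibility={self.mean_visibility:.2f}, "
            f"mean recovery={self.mean_sequence_recovery:.3f}, "
            f"mean TM-score={tm}"
        )


def evaluate_checkpoint(
    model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    predictor: PresentationPredictor,
    structure_backend: StructurePredictionBackend | None = None,
    protocol: str = "single",
    n_candidates: int = 3,
    temperature: float = 0.1,
    tm_threshold: float = 0.9,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    checkpoint_id: str = "",
    hyperparams: dict | None = None,
) -> TradeoffRecord:
    """Evaluate one checkpoint over an evaluation set.

    ``protocol='single'`` samples one design per structure (large general
    sets); ``protocol='select3'`` runs the full candidate-generation,
    diversity-filter, structure-prediction and selection pipeline (small
    specific sets).  TM-scores are computed only when a structure backend is
    available; failed predictions score 0 and the run continues.  Mean
    relative visibility is the mean of per-structure ratios.
    """
    if not structures:
        raise ValueError("evaluation set must not be empty")
    if protocol not in ("single", "select3"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for s in structures:
        if s.sequence is None:
            raise ValueError("evaluation structures need native sequences")
        template_vis = absolute_visibility(s.sequence, predictor).absolute_visibility
        if protocol == "single":
            cands = generate_candidates(
                model, s, predictor, n=1, temperature=temperature, rng=rng
            )
            design = cands[0]
            if structure_backend is not None:
                pred = structure_backend.predict(design.sequence, s)
                design.tm_score = 0.0 if pred is None else tm_score_builtin(s, pred)
                design.predicted_structure = pred
        else:
            cands = generate_candidates(
                model, s, predictor, n=n_candidates, temperature=temperature, rng=rng
            )
            cands = filter_low_diversity(cands)
            for c in cands:
                if structure_backend is None:
                    raise ValueError("protocol 'select3' needs a structure backend")
                pred = structure_backend.predict(c.sequence, s)
                c.tm_score = 0.0 if pred is None else tm_score_builtin(s, pred)
                c.predicted_structure = pred
            design = select_design(cands, tm_threshold=tm_threshold)
            if design is None:  # every candidate was low-diversity: failed design
                rows.append(
                    {
                        "structure": s.name,
                        "template_visibility": template_vis,
                        "visibility": np.nan,
                        "relative_visibility": np.nan,
                        "sequence_recovery": np.nan,
                        "tm_score": 0.0,
                        "failed": True,
                    }
                )
                continue
        rows.append(
            {
                "structure": s.name,
                "template_visibility": template_vis,
                "visibility": design.visibility,
                "relative_visibility": relative_visibility(
                    design.visibility, template_vis
                ),
                "sequence_recovery": sequence_recovery(design.sequence, s.sequence),
                "tm_score": design.tm_score,
                "failed": False,
            }
        )
    df = pd.DataFrame(rows)
    ok = ~df["failed"]
    tm_vals = df.loc[ok, "tm_score"].dropna()
    return TradeoffRecord(
        checkpoint_id=checkpoint_id,
        n_structures=len(structures),
        mean_relative_visibility=float(np.nanmean(df.loc[ok, "relative_visibility"])),
        mean_visibility=float(np.nanmean(df.loc[ok, "visibility"])),
        mean_sequence_recovery=float(np.nanmean(df.loc[ok, "sequence_recovery"])),
        mean_tm_score=float(tm_vals.mean()) if len(tm_vals) else None,
        per_structure=df,
        hyperparams=hyperparams or {},
    )


#: netMHCpan rank-category bin edges, as rank fractions (0.02 = 2% rank).
#: The first bin holds "strong binders", the second "weak binders"; higher
#: bins are predicted not presented.
RANK_BINS: tuple[float, ...] = (0.0, 0.005, 0.02, 0.05, 0.1, 0.25, 0.5, 1.0)


def rank_category_histogram(
    sequence: str,
    rank_predictor: Callable[[str], float],
    bins: Iterable[float] = RANK_BINS,
    lengths: Iterable[int] = (8, 9, 10),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of best per-k-mer presentation ranks.

    *rank_predictor* maps a peptide to its best rank (fraction in [0, 1])
    across the patient's alleles — e.g.
    :meth:`deimmune.netmhcpan.NetMHCpanPredictor.best_rank` (divided by 100)
    or a synthetic rank oracle.  The bins partition all scanned k-mers:
    counts sum to the total window count.
    """
    from .visibility import enumerate_kmers

    edges = np.asarray(sorted(bins), dtype=float)
    ranks = [rank_predictor(pep) for _, _, pep in enumerate_kmers(sequence, lengths)]
    counts, _ = np.histogram(np.clip(ranks, edges[0], edges[-1]), bins=edges)
    return counts, edges


def plot_tradeoff(records: Sequence[TradeoffRecord], ax=None, metric: str = "recovery"):
    """Scatter of mean relative visibility vs design quality per checkpoint.

    ``metric`` is ``'recovery'`` or ``'tm'``.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [r.mean_relative_visibility for r in records]
    if metric == "recovery":
        ys = [r.mean_sequence_recovery for r in records]
        ax.set_ylabel("mean sequence recovery")
    elif metric == "tm":
        ys = [math.nan if r.mean_tm_score is None else r.mean_tm_score for r in records]
        ax.set_ylabel("mean TM-score")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ax.scatter(xs, ys)
    for r, x, y in zip(records, xs, ys):
        ax.annotate(r.checkpoint_id, (x, y), fontsize=7)
    ax.set_xlabel("mean relative visibility")
    return ax
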