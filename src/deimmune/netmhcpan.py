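"""Optional adapter for an external netMHCpan executable.

The adapter batches peptides through the standard peptide-list input
(``-p`` mode), collects the eluted-ligand percentile rank per allele, and
pools alleles by taking each peptide's best (lowest) rank.  A peptide is
called presented when its best rank is at or below the cutoff: 2.0 (percent)
includes "weak binders", 0.5 restricts to "strong binders".

The executable is not bundled; :func:`is_available` probes the PATH and all
entry points raise a clear error when it is missing, so the feature degrades
to a disabled state with a message rather than silently returning values.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .alphabet import UNCLEAR, UNKNOWN, validate_peptide
from .presentation import PresentationCall

__all__ = [
    "DEFAULT_ALLELES",
    "WEAK_BINDER_RANK",
    "STRONG_BINDER_RANK",
    "is_available",
    "parse_peptide_ranks",
    "NetMHCpanPredictor",
]

#: The six MHC-I alleles of the hypothetical patient used throughout.
DEFAULT_ALLELES: tuple[str, ...] = (
    "HLA-A02:01",
    "HLA-A24:02",
    "HLA-B07:02",
    "HLA-B39:01",
    "HLA-C07:01",
    "HLA-C16:01",
)

WEAK_BINDER_RANK = 2.0  # percent
STRONG_BINDER_RANK = 0.5  # percent


def is_available(executable: str = "netMHCpan") -> bool:
    """True if the external executable is on the PATH."""
    return shutil.which(executable) is not None


def parse_peptide_ranks(text: str) -> dict[str, float]:
    """Parse peptide -> %Rank_EL from one netMHCpan run's standard output.

    Locates the header line to find the ``Peptide`` and ``%Rank_EL`` (or
    legacy ``%Rank``) columns, then reads every subsequent data row (rows
    start with a numeric position field).
    """
    pep_col = rank_col = None
    ranks: dict[str, float] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if "Peptide" in fields and any(f.startswith("%Rank") for f in fields):
            pep_col = fields.index("Peptide")
            rank_col = next(
                i for i, f in enumerate(fields) if f.startswith("%Rank")
            )
            continue
        if pep_col is None or not fields[0].lstrip("-").isdigit():
            continue
        try:
            peptide = fields[pep_col]
            rank = float(fields[rank_col])
        except (IndexError, ValueError):
            continue
        ranks[peptide] = min(rank, ranks.get(peptide, float("inf")))
    if pep_col is None:
        raise ValueError("no netMHCpan result header found in output")
    return ranks


@dataclass
class NetMHCpanPredictor:
    """Presentation predictor backed by an external netMHCpan binary."""

    alleles: Sequence[str] = DEFAULT_ALLELES
    rank_cutoff: float = WEAK_BINDER_RANK
    executable: str = "netMHCpan"
    name: str = "netMHCpan"
    _cache: dict[str, float] = field(default_factory=dict, repr=False)

    def _require(self) -> str:
        exe = shutil.which(self.executable)
        if exe is None:
            raise RuntimeError(
                f"netMHCpan executable {self.executable!r} not found on PATH; "
                "install it or use the PWM classifier / motif oracle instead"
            )
        return exe

    def best_ranks(self, peptides: Sequence[str]) -> dict[str, float]:
        """Best (lowest) percentile rank per peptide across the alleles."""
        exe = self._require()
        todo = [p for p in dict.fromkeys(peptides) if p not in self._cache]
        if todo:
            with tempfile.TemporaryDirectory() as tmp:
                pep_file = Path(tmp) / "peptides.txt"
                pep_file.write_text("\n".join(todo) + "\n")
                for allele in self.alleles:
                    proc = subprocess.run(
                        [exe, "-p", str(pep_file), "-a", allele],
                        capture_output=True,
                        text=True,
                        check=True,
                    )
                    for pep, rank in parse_peptide_ranks(proc.stdout).items():
                        self._cache[pep] = min(rank, self._cache.get(pep, float("inf")))
        return {p: self._cache[p] for p in peptides}

    def best_rank(self, peptide: str) -> float:
        """Best percentile rank (percent units) for one peptide."""
        return self.best_ranks([peptide])[peptide]

    def best_rank_fraction(self, peptide: str) -> float:
        """Best rank as a fraction in [0, 1] (for rank-category histograms)."""
        return min(self.best_rank(peptide) / 100.0, 1.0)

    def __call__(self, peptide: str) -> PresentationCall:
        validate_peptide(peptide)
        if UNKNOWN in peptide:
            return UNCLEAR
        return self.best_rank(peptide) <= self.rank_cutoff
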