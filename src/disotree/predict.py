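"""Per-residue disorder prediction plumbing.

External predictors (VSL2P, ESpritz, IUPred, the PONDR family, ...) are
web services or closed tools; their scores enter the pipeline as CSV
files via :mod:`disotree.seqio`.  This module supplies the pieces the
pipeline itself owns:

* a pluggable predictor contract (any callable sequence -> profile can
  be registered by name),
* a transparent bundled predictor — a sliding-window mean of the
  TOP-IDP per-residue disorder propensity scale pushed through a
  logistic squash — so the whole pipeline runs self-contained.  It makes
  no claim of numeric agreement with any published predictor,
* amino-acid substitution handling and mutant-minus-wild-type
  difference profiles for mutation scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ProfileMismatchError, StaleCoordinatesError
from .seqio import DisorderProfile, SequenceRecord

# TOP-IDP disorder propensity scale (Campen et al. 2008): positive values
# favour disorder, negative favour order.
TOP_IDP: dict[str, float] = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}
_TOP_IDP_MEAN = sum(TOP_IDP.values()) / len(TOP_IDP)


def _logistic(x: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (x - midpoint)))


@dataclass(frozen=True)
class PredictorSpec:
    """A windowed propensity-scale disorder predictor.

    The score of residue i is ``squash(mean propensity over the window
    centred on i)``, the window truncated at the termini.  ``window``
    must be odd so the window is centred.
    """

    name: str = "topidp-w21"
    window: int = 21
    propensity_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(TOP_IDP)
    )
    squash_midpoint: float = _TOP_IDP_MEAN
    squash_steepness: float = 4.0

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.propensity_scale)
        if missing:
            raise ValueError(f"scale undefined for residues {sorted(missing)}")

    def propensity(self, residue: str) -> float:
        if residue == "X":  # unknown residue scores the scale mean
            return sum(self.propensity_scale[a] for a in self.propensity_scale) / len(
                self.propensity_scale
            )
        return self.propensity_scale[residue]


def predict_profile(
    seq: SequenceRecord, spec: PredictorSpec | None = None
) -> DisorderProfile:
    """Deterministic windowed-mean disorder profile for one sequence."""
    spec = spec or PredictorSpec()
    prop = np.array([spec.propensity(ch) for ch in seq.residues])
    half = (spec.window - 1) // 2
    n = prop.size
    # window truncated at the termini: mean over the available neighbours.
    # Computed per slice (not via prefix sums) so positions whose windows
    # exclude a substitution are bit-identical between wild type and mutant.
    means = np.array(
        [prop[max(i - half, 0) : i + half + 1].mean() for i in range(n)]
    )
    scores = _logistic(means, spec.squash_midpoint, spec.squash_steepness)
    return DisorderProfile(seq.id, np.clip(scores, 0.0, 1.0))


# ----------------------------------------------------------------------
# predictor registry
# ----------------------------------------------------------------------
Predictor = Callable[[SequenceRecord], DisorderProfile]

_REGISTRY: dict[str, Predictor] = {}


def register_predictor(name: str, fn: Predictor) -> None:
    _REGISTRY[name] = fn


def get_predictor(name: str) -> Predictor:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no predictor {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_predictor("topidp-w21", lambda seq: predict_profile(seq, PredictorSpec()))


# ----------------------------------------------------------------------
# substitutions and difference profiles
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Substitution:
    """A point substitution (1-based position, wild-type and mutant residue)."""

    position: int
    wt: str
    mut: str

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError(f"{self}: wild-type and mutant residue identical")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        """Parse compact notation such as ``T58A``."""
        wt, mut = text[0], text[-1]
        return cls(position=int(text[1:-1]), wt=wt, mut=mut)


# Functionally significant cancer-associated substitutions in the human
# c-Myc transactivation domain; the default mutation set for scans.
CMYC_CANCER_SUBSTITUTIONS: tuple[Substitution, ...] = tuple(
    Substitution.parse(s)
    for s in ("E39D", "A44V", "P57S", "T58I", "T58A", "S62P", "S71W")
)


def apply_substitutions(
    seq: SequenceRecord, subs: Sequence[Substitution]
) -> SequenceRecord:
    """Return a mutated copy of the sequence; length is unchanged.

    Each substitution's stated wild-type residue must match the sequence
    at its position — a mismatch means the coordinates are stale (e.g.
    numbered on a different isoform) and raises rather than silently
    mutating the wrong residue.
    """
    residues = list(seq.residues)
    seen_positions = set()
    for sub in subs:
        if not (1 <= sub.position <= len(residues)):
            raise StaleCoordinatesError(
                f"{sub}: position outside sequence of length {len(residues)}"
            )
        if sub.position in seen_positions:
            raise StaleCoordinatesError(f"{sub}: duplicate position")
        if residues[sub.position - 1] != sub.wt:
            raise StaleCoordinatesError(
                f"{sub}: sequence has {residues[sub.position - 1]!r} at "
                f"position {sub.position}, expected {sub.wt!r}"
            )
        residues[sub.position - 1] = sub.mut
        seen_positions.add(sub.position)
    return SequenceRecord(seq.id, "".join(residues))


def delta_profile(wt: DisorderProfile, mut: DisorderProfile) -> np.ndarray:
    """Signed per-residue difference series: mutant minus wild type."""
    if len(wt) != len(mut):
        raise ProfileMismatchError(
            f"profiles differ in length ({len(wt)} vs {len(mut)})"
        )
    return mut.scores - wt.scores
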