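"""The seven sequence physico-chemical properties and the property score.

All seven properties are composition-based (invariant under residue
reordering):

* molar extinction coefficient at 280 nm (Gill-von Hippel, oxidized
  cystines);
* absorbance (extinction coefficient divided by molecular weight — the
  optical density of a 1 g/L solution over a 1 cm path);
* counts of negatively (D, E) and positively (R, K) charged residues;
* aliphatic index (Ikai);
* isoelectric point divided by molecular weight in kDa;
* GRAVY (mean Kyte-Doolittle hydropathy).

Because the raw properties span several orders of magnitude, comparisons are
made on z-scored vectors standardized against a stated reference population
(in the pipeline: the target's refined neighborhood).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import constants as C

PROPERTY_NAMES = (
    "e_protein",
    "absorbance",
    "n_neg",
    "n_pos",
    "aliphatic_index",
    "ip_over_mw",
    "gravy",
)


def _validate(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(C.AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)}")
    return seq


def extinction_coefficient(seq: str) -> float:
    """280 nm molar extinction coefficient; paired cysteines only."""
    seq = _validate(seq)
    return float(
        C.EXTINCTION_TRP * seq.count("W")
        + C.EXTINCTION_TYR * seq.count("Y")
        + C.EXTINCTION_CYSTINE * (seq.count("C") // 2)
    )


def molecular_weight(seq: str) -> float:
    """Average-mass molecular weight in daltons (residue masses + one water)."""
    seq = _validate(seq)
    # summed per residue type so the result is exactly order-independent
    return sum(C.AVERAGE_RESIDUE_MASS[aa] * seq.count(aa)
               for aa in C.AMINO_ACIDS) + C.WATER_MASS


def absorbance(seq: str) -> float:
    return extinction_coefficient(seq) / molecular_weight(seq)


def charge_counts(seq: str) -> tuple[int, int]:
    """(n_negative, n_positive): D+E and R+K counts; His excluded."""
    seq = _validate(seq)
    n_neg = sum(seq.count(aa) for aa in C.NEGATIVE_RESIDUES)
    n_pos = sum(seq.count(aa) for aa in C.POSITIVE_RESIDUES)
    return n_neg, n_pos


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index over mole-percent composition; range [0, 390]."""
    seq = _validate(seq)
    n = len(seq)
    x_ala = 100.0 * seq.count("A") / n
    x_val = 100.0 * seq.count("V") / n
    x_il = 100.0 * (seq.count("I") + seq.count("L")) / n
    return x_ala + C.ALIPHATIC_VAL_COEF * x_val + C.ALIPHATIC_ILE_LEU_COEF * x_il


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini + side chains)."""
    seq = _validate(seq)
    charge = 1.0 / (1.0 + 10 ** (ph - C.PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (C.PKA_CTERM - ph))
    for aa, pka in sorted(C.PKA_SIDECHAIN_BASIC.items()):
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in sorted(C.PKA_SIDECHAIN_ACIDIC.items()):
        charge -= seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4, max_iter: int = 100) -> float:
    """pH of zero net charge, solved by bisection on the monotone charge curve."""
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            return mid
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("isoelectric-point bisection did not converge")


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    seq = _validate(seq)
    return sum(C.KYTE_DOOLITTLE[aa] * seq.count(aa)
               for aa in C.AMINO_ACIDS) / len(seq)


@dataclass(frozen=True)
class PropertyVector:
    """The seven raw physico-chemical values for one sequence."""

    e_protein: float
    absorbance: float
    n_neg: int
    n_pos: int
    aliphatic_index: float
    ip_over_mw: float
    gravy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROPERTY_NAMES], dtype=float)


def compute_properties(seq: str) -> PropertyVector:
    n_neg, n_pos = charge_counts(seq)
    mw_kda = molecular_weight(seq) / 1000.0
    return PropertyVector(
        e_protein=extinction_coefficient(seq),
        absorbance=absorbance(seq),
        n_neg=n_neg,
        n_pos=n_pos,
        aliphatic_index=aliphatic_index(seq),
        ip_over_mw=isoelectric_point(seq) / mw_kda,
        gravy=gravy(seq),
    )


@dataclass(frozen=True)
class PropertyScore:
    """Z-scored property vector plus its scalar summary (mean of components)."""

    vector: np.ndarray
    scalar: float
    population_size: int


def _population_stats(population: Sequence[PropertyVector]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.vstack([v.as_array() for v in population])
    return mat.mean(axis=0), mat.std(axis=0)


def zscore_vector(vec: PropertyVector, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    raw = vec.as_array()
    out = np.zeros_like(raw)
    nonzero = std > 0
    out[nonzero] = (raw[nonzero] - mean[nonzero]) / std[nonzero]
    return out


def property_score(vec: PropertyVector, population: Sequence[PropertyVector]) -> PropertyScore:
    """Standardize one vector against a reference population (>= 2 members).

    Components with zero population variance map to 0; the scalar score is
    the arithmetic mean of the seven standardized components.
    """
    if len(population) < 2:
        raise ValueError("reference population must contain at least 2 vectors")
    mean, std = _population_stats(population)
    z = zscore_vector(vec, mean, std)
    return PropertyScore(vector=z, scalar=float(z.mean()), population_size=len(population))


def standardize_population(
    vectors: dict[str, PropertyVector],
    population_ids: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Z-score every vector against the stated population (default: all keys)."""
    ids = sorted(vectors) if population_ids is None else sorted(population_ids)
    if len(ids) < 2:
        raise ValueError("reference population must contain at least 2 vectors")
    mean, std = _population_stats([vectors[i] for i in ids])
    return {name: zscore_vector(vec, mean, std) for name, vec in vectors.items()}
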