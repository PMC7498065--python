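"""Peptide mass prediction for knob domains, with disulphide correction.

Knob-domain peptides are identified in LC/MS by matching observed charge
envelopes against predictions computed from the amino-acid sequence with
all cysteines assumed oxidised in pairs: each disulphide bond removes two
hydrogens (-2 x 1.00782503 Da).  Predictions cover the monoisotopic and
average mass, m/z per charge state ((M + z*mp)/z with the proton mass
mp = 1.00727646 Da), and the isotope envelope obtained by iterative
convolution of the per-element isotope distributions on the nucleon grid
(peak spacing one neutron mass / z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as pmass

PROTON_MASS = 1.00727646
HYDROGEN_MASS = 1.00782503
NEUTRON_MASS = 1.00866491588

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts (C, H, N, O, S and any further elements)."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for el, n in self.counts:
            if n < 0 or n != int(n):
                raise ValueError(f"invalid count {el}{n}")

    @classmethod
    def from_dict(cls, d: dict) -> "ElementalFormula":
        return cls(tuple(sorted((el, int(n)) for el, n in d.items() if n)))

    def as_dict(self) -> dict:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = dict(self.counts)
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula.from_dict(d)

    @property
    def monoisotopic_mass(self) -> float:
        return pmass.calculate_mass(composition=pmass.Composition(self.as_dict()))

    @property
    def average_mass(self) -> float:
        return pmass.calculate_mass(composition=pmass.Composition(self.as_dict()),
                                    average=True)


def peptide_formula(aa: str) -> ElementalFormula:
    """Elemental formula of a linear peptide (residues + one water)."""
    for i, res in enumerate(aa):
        if res not in _STANDARD_AA:
            raise ValueError(f"non-standard residue {res!r} at position {i}")
    comp = pmass.Composition(sequence=aa)
    return ElementalFormula.from_dict(dict(comp))


def apply_disulphides(formula: ElementalFormula,
                      n_disulphides: int) -> ElementalFormula:
    """Remove two hydrogens per disulphide bond."""
    if n_disulphides < 0:
        raise ValueError("n_disulphides must be >= 0")
    h = formula["H"]
    if h < 2 * n_disulphides:
        raise ValueError(
            f"formula has {h} H, cannot form {n_disulphides} disulphides")
    d = formula.as_dict()
    d["H"] = h - 2 * n_disulphides
    return ElementalFormula.from_dict(d)


def charge_state_mz(monoisotopic_mass: float, z: int) -> float:
    """(M + z * proton) / z for positive-mode electrospray."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass + z * PROTON_MASS) / z


def _element_distribution(el: str) -> np.ndarray:
    """Natural isotope abundances on the nucleon grid (index 0 = lightest)."""
    isotopes = {k: v for k, v in pmass.nist_mass[el].items()
                if k != 0 and v[1] > 0}
    nums = sorted(isotopes)
    arr = np.zeros(nums[-1] - nums[0] + 1)
    for n in nums:
        arr[n - nums[0]] = isotopes[n][1]
    return arr


def _convolve_power(base: np.ndarray, n: int, prune: float = 1e-12,
                    ) -> np.ndarray:
    """base convolved with itself n times (binary exponentiation)."""
    result = np.array([1.0])
    power = base
    while n:
        if n & 1:
            result = np.convolve(result, power)
            result[result < prune] = 0.0
        power = np.convolve(power, power)
        power[power < prune] = 0.0
        n >>= 1
    return result


def isotope_envelope(formula: ElementalFormula, z: int,
                     abundance_floor: float = 1e-4,
                     ) -> list[tuple[float, float]]:
    """Isotope envelope as (m/z, relative abundance) pairs.

    Abundances are normalised so the tallest peak is 1 and the envelope is
    truncated at *abundance_floor*; peaks are spaced one neutron mass / z
    above the monoisotopic peak, which always comes first.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    dist = np.array([1.0])
    for el, n in formula.counts:
        dist = np.convolve(dist, _convolve_power(_element_distribution(el), n))
    dist = dist / dist.max()
    mono = formula.monoisotopic_mass
    peaks = [((mono + k * NEUTRON_MASS + z * PROTON_MASS) / z, a)
             for k, a in enumerate(dist) if a >= abundance_floor]
    return peaks


@dataclass(frozen=True)
class MassPrediction:
    peptide: str
    formula: ElementalFormula
    n_disulphides: int
    monoisotopic_mass: float
    average_mass: float
    charge_states: tuple[tuple[int, float], ...]
    envelopes: tuple[tuple[int, tuple[tuple[float, float], ...]], ...] = field(
        default=())

    @classmethod
    def predict(cls, aa: str, n_disulphides: int | None = None,
                charges: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                with_envelopes: bool = False) -> "MassPrediction":
        """Predict masses for a peptide; by default all cysteines are
        assumed oxidised in pairs (n_disulphides = floor(nCys / 2))."""
        n_cys = aa.count("C")
        if n_disulphides is None:
            n_disulphides = n_cys // 2
        if 2 * n_disulphides > n_cys:
            raise ValueError(
                f"{n_disulphides} disulphides need {2 * n_disulphides} Cys, "
                f"peptide has {n_cys}")
        formula = apply_disulphides(peptide_formula(aa), n_disulphides)
        mono = formula.monoisotopic_mass
        envs = ()
        if with_envelopes:
            envs = tuple((z, tuple(isotope_envelope(formula, z)))
                         for z in charges)
        return cls(peptide=aa, formula=formula, n_disulphides=n_disulphides,
                   monoisotopic_mass=mono, average_mass=formula.average_mass,
                   charge_states=tuple((z, charge_state_mz(mono, z))
                                       for z in charges),
                   envelopes=envs)
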