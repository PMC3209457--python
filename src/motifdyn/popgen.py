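"""Hardy–Weinberg arithmetic for an autosomal-recessive allele.

Connects allele frequency p, carrier (heterozygote) frequency and affected
homozygote frequency under random mating:

    genotype frequencies  (1−p)²,  2p(1−p),  p².

Two conventions are supported for the carrier frequency.  ``exact`` uses
2p(1−p).  ``rare_approx`` uses 2p — the approximation customary in clinical
genetics when p is small, and the one under which the textbook chain
"allele frequency 0.004 → carrier 1 in 125 (0.8%) → affected homozygote
1 in 62,500" is exact; it is therefore the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = ["HWResult", "from_allele_freq", "from_carrier_freq"]

Convention = Literal["exact", "rare_approx"]


@dataclass(frozen=True)
class HWResult:
    """Allele, carrier and affected-homozygote frequencies plus their
    "1 in N" forms."""

    allele_freq: float
    carrier_freq: float
    homozygote_freq: float
    one_in_n_carrier: float
    one_in_n_homozygote: float
    convention: Convention

    def genotype_freqs(self) -> tuple[float, float, float]:
        """(homozygous reference, heterozygote, homozygous alternate) under
        the exact Hardy–Weinberg law (independent of the carrier convention)."""
        p = self.allele_freq
        q = 1.0 - p
        return (q * q, 2.0 * p * q, p * p)


def from_allele_freq(p: float, convention: Convention = "rare_approx") -> HWResult:
    """Carrier and homozygote frequencies implied by allele frequency ``p``.

    >>> r = from_allele_freq(0.004)
    >>> r.one_in_n_carrier, r.one_in_n_homozygote
    (125.0, 62500.0)
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    if convention == "exact":
        carrier = 2.0 * p * (1.0 - p)
    elif convention == "rare_approx":
        carrier = 2.0 * p
    else:
        raise ValueError(f"unknown convention {convention!r}")
    homozygote = p * p
    return HWResult(
        allele_freq=p,
        carrier_freq=carrier,
        homozygote_freq=homozygote,
        one_in_n_carrier=1.0 / carrier,
        one_in_n_homozygote=1.0 / homozygote,
        convention=convention,
    )


def from_carrier_freq(carrier: float, convention: Convention = "rare_approx") -> HWResult:
    """Invert the carrier convention to the allele frequency, then as
    :func:`from_allele_freq`.

    ``rare_approx`` inverts p = carrier / 2.  ``exact`` solves
    2p(1−p) = carrier for the smaller root, which exists only for
    carrier ≤ 0.5.

    >>> r = from_carrier_freq(0.0135)
    >>> round(r.one_in_n_homozygote)
    21948
    """
    if not 0.0 < carrier < 1.0:
        raise ValueError(f"carrier frequency must be in (0, 1), got {carrier}")
    if convention == "rare_approx":
        p = carrier / 2.0
    elif convention == "exact":
        if carrier > 0.5:
            raise ValueError(
                f"exact convention admits no allele frequency for carrier "
                f"frequency {carrier} > 0.5"
            )
        # smaller root of 2p² − 2p + carrier = 0
        p = 0.5 * (1.0 - (1.0 - 2.0 * carrier) ** 0.5)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return from_allele_freq(p, convention)
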