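"""Genotype handling: map (gene, variant, zygosity) to species-pool allocations.

The model treats GNAQ and GNA11 as biochemically identical, each contributing
half of the total G-alpha pool.  A heterozygous mutation in one of the two
genes therefore converts a quarter of the total pool to mutant protein
(one of the mutated gene's two alleles), and a homozygous mutation converts
that gene's entire half.  Receptor (CYSLTR2) mutations leave the G-alpha pool
untouched and instead split the receptor population: heterozygous L129Q is
modeled as 50% WT / 50% mutant receptor.  Total protein abundances are never
changed by genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    GALPHA_VARIANTS,
    RECEPTOR_VARIANTS,
    ModelParameters,
    VariantScalings,
)

__all__ = ["GenotypeSpec", "PoolAllocation", "allocate", "parse_genotype", "WT"]

GALPHA_GENES = ("GNAQ", "GNA11")
RECEPTOR_GENE = "CYSLTR2"
GENES = GALPHA_GENES + (RECEPTOR_GENE,)
ZYGOSITIES = ("het", "hom")


@dataclass(frozen=True)
class GenotypeSpec:
    """A single-lesion genotype: gene, variant and zygosity.

    ``variant == "WT"`` denotes the all-wild-type genotype regardless of gene
    and zygosity.
    """

    gene: str = "GNAQ"
    variant: str = "WT"
    zygosity: str = "het"

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; choose from {GENES}")
        if self.variant != "WT":
            if self.zygosity not in ZYGOSITIES:
                raise ValueError(
                    f"zygosity must be one of {ZYGOSITIES}, got {self.zygosity!r}"
                )
            if self.variant in GALPHA_VARIANTS:
                if self.gene not in GALPHA_GENES:
                    raise ValueError(
                        f"variant {self.variant} occurs on GNAQ/GNA11, not {self.gene}"
                    )
            elif self.variant in RECEPTOR_VARIANTS:
                if self.gene != RECEPTOR_GENE:
                    raise ValueError(
                        f"variant {self.variant} occurs on {RECEPTOR_GENE}, "
                        f"not {self.gene}"
                    )
            else:
                raise ValueError(
                    f"unknown variant {self.variant!r}; known G-alpha variants "
                    f"{GALPHA_VARIANTS}, receptor variants {RECEPTOR_VARIANTS}"
                )

    @property
    def is_wt(self) -> bool:
        return self.variant == "WT"

    def __str__(self) -> str:
        if self.is_wt:
            return "WT"
        return f"{self.gene}:{self.variant}:{self.zygosity}"


#: Convenience all-wild-type genotype.
WT = GenotypeSpec()


def parse_genotype(text: str) -> GenotypeSpec:
    """Parse the ``GENE:VARIANT:ZYGOSITY`` string syntax (``"WT"`` accepted)."""
    text = text.strip()
    if text.upper() == "WT":
        return WT
    parts = text.split(":")
    if len(parts) == 2:
        gene, variant = parts
        zygosity = "het"
    elif len(parts) == 3:
        gene, variant, zygosity = parts
    else:
        raise ValueError(
            f"cannot parse genotype {text!r}; expected GENE:VARIANT[:ZYGOSITY]"
        )
    return GenotypeSpec(gene=gene.upper(), variant=variant, zygosity=zygosity.lower())


@dataclass(frozen=True)
class PoolAllocation:
    """Fractions of the G-alpha and receptor pools assigned to mutant protein,
    together with the mutant parameter-scaling bundle."""

    galpha_mut_frac: float
    receptor_mut_frac: float
    scalings: VariantScalings

    def __post_init__(self):
        for name in ("galpha_mut_frac", "receptor_mut_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def allocate(genotype: GenotypeSpec, params: ModelParameters) -> PoolAllocation:
    """Translate a genotype into mutant pool fractions and scalings.

    G-alpha variants: het -> 25% of the total G-alpha pool is mutant (one of
    the four alleles across the two identical genes), hom -> 50% (the mutated
    gene's entire share).  Receptor variants: het -> 50% mutant receptor,
    hom -> 100% (flagged experimental; only the heterozygous case is backed by
    tumor genomics).
    """
    if genotype.is_wt:
        return PoolAllocation(0.0, 0.0, VariantScalings())
    scalings = params.scalings_for(genotype.variant)
    if genotype.variant in GALPHA_VARIANTS:
        frac = 0.25 if genotype.zygosity == "het" else 0.50
        return PoolAllocation(frac, 0.0, scalings)
    frac = 0.50 if genotype.zygosity == "het" else 1.0
    return PoolAllocation(0.0, frac, scalings)
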