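"""Genetic-load and mutation-budget arithmetic.

Under truncation selection against recurrent deleterious mutation, the
fractional reduction of mean fitness is ``L = 1 - exp(-U)`` where ``U`` is
the number of new deleterious mutations per diploid genome per generation.
The mutation-budget helpers turn per-site rates and replicore counts into
per-generation mutation numbers; they are exact products, nothing more.
"""

from __future__ import annotations

import math

__all__ = ["genetic_load", "mutations_per_generation", "cell_level_mutations"]


def genetic_load(U: float) -> float:
    """Genetic load ``L = 1 - exp(-U)`` under truncation selection.

    Parameters
    ----------
    U : float
        New deleterious mutations per diploid genome per generation (>= 0).

    Returns
    -------
    float
        Load in ``[0, 1)``: the fraction of the population that must be
        removed each generation to purge the mutational input. ``U = 0``
        gives 0; the load approaches 1 as ``U`` grows (population extinction).

    Notes
    -----
    Survival probabilities multiply, so the load composes as
    ``genetic_load(a + b) = 1 - (1 - genetic_load(a)) * (1 - genetic_load(b))``.
    For humans the literature value ``U = 2.2`` gives ``L = 0.89`` (2 dp).
    """
    if U < 0:
        raise ValueError(f"U must be non-negative, got {U}")
    return -math.expm1(-U)


def mutations_per_generation(
    rate_per_site_per_year: float, genome_size_bp: float, generation_years: float
) -> float:
    """Expected new mutations per generation: rate x genome size x generation time.

    All three inputs must be positive. With the human figures
    (1e-9 per site per year, 3e9 bp, 20-25 years) this gives 60-75.
    """
    for name, v in (
        ("rate_per_site_per_year", rate_per_site_per_year),
        ("genome_size_bp", genome_size_bp),
        ("generation_years", generation_years),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return rate_per_site_per_year * genome_size_bp * generation_years


def cell_level_mutations(replicore_count: float, mutations_per_replicore: float) -> float:
    """Cell-level mutation count: replicore count x mutations per replicore.

    Inputs must be non-negative. 10,000 replicores at 0.01 mutations each
    gives 100 mutations per generation at the cellular level, even though
    each individual replicore sits far below the error threshold.
    """
    for name, v in (
        ("replicore_count", replicore_count),
        ("mutations_per_replicore", mutations_per_replicore),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return replicore_count * mutations_per_replicore
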