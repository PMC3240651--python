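"""Synthetic p53TAD-like homologue family for end-to-end runs.

Only the human p53 transactivation domain sequence (residues 1-73 of the
canonical human p53) is real; every other "homologue" here is generated by
seeded substitution of that anchor and is a synthetic stand-in for the real
mammalian family, preserving the features the pipeline exercises — proline
content and placement (prolines have no measurable NOE), the composition
skew toward E/L/P/S, and graded pairwise identity.  Nothing in this module
reproduces a real non-human p53 sequence.
"""

from __future__ import annotations

import numpy as np

from .io import AMINO_ACIDS, SequenceRecord

__all__ = ["human_p53tad", "synthetic_homologue", "synthetic_family"]

# canonical human p53, residues 1-73 (the transactivation domain construct)
_HUMAN_P53TAD = (
    "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGPDEAPRMPEAAPPV"
)

# substitutions stay proline-neutral so the unmeasurable-residue pattern of
# the family is conserved
_NON_PROLINE = AMINO_ACIDS.replace("P", "")


def human_p53tad() -> SequenceRecord:
    """The human p53 transactivation domain, residues 1-73."""
    return SequenceRecord(identifier="human", residues=_HUMAN_P53TAD)


def synthetic_homologue(
    identifier: str, n_substitutions: int, seed: int
) -> SequenceRecord:
    """A synthetic homologue: the human anchor with seeded substitutions.

    Exactly ``n_substitutions`` non-proline positions are changed to a
    different non-proline residue, so identity to human is
    ``100 * (73 - n_substitutions) / 73`` and the proline pattern is intact.
    """
    rng = np.random.default_rng(seed)
    residues = list(_HUMAN_P53TAD)
    candidates = [i for i, aa in enumerate(residues) if aa != "P"]
    if n_substitutions > len(candidates):
        raise ValueError("more substitutions than non-proline positions")
    picks = rng.choice(len(candidates), size=n_substitutions, replace=False)
    for idx in picks:
        pos = candidates[idx]
        choices = [aa for aa in _NON_PROLINE if aa != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return SequenceRecord(identifier=identifier, residues="".join(residues))


def synthetic_family(seed: int = 0) -> list[SequenceRecord]:
    """Six p53TAD-like sequences: the human anchor plus five synthetic
    homologues at graded divergence (a macaque-like near-identical partner
    down to rodent-like divergence)."""
    plan = [
        ("macaque_like", 6),
        ("dog_like", 14),
        ("cow_like", 18),
        ("rabbit_like", 22),
        ("mouse_like", 28),
    ]
    family = [human_p53tad()]
    for offset, (name, subs) in enumerate(plan):
        family.append(synthetic_homologue(name, subs, seed + offset))
    return family
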