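"""Ready-made pools, schedules and structure fixtures for the worked examples.

The species tables and structure constraint counts used here are the
running examples of this package's documentation and test suite: a
four-catalyst pool spanning the amplitude/rate trade-off, the stepped
stringency schedule (tau = 5 for five rounds, then divided by 5 per
round), a cofactor-dependence trio for counter-selection, and structure
fixtures with the constraint counts of three well-characterized
ribozyme motifs (hammerhead, twister, and the smallest known
self-triphosphorylation ribozyme).

The structure fixtures encode only the counts (Lstr, s, b, module
layout, anchoring): the closed-form frequencies depend on counts alone,
so conserved/paired positions are laid out at convenient coordinates
(with pairs inside modules) rather than at the motifs' literal
positions.
"""

from __future__ import annotations

from .kinetics import ReactionParams
from .selection import CofactorPool, CofactorSpecies, SpeciesPool, TauSchedule
from .structure import StructureConstraint

__all__ = [
    "example_catalysts",
    "example_pool",
    "cofactor_pool",
    "constant_schedule",
    "stepped_schedule",
    "hammerhead_structure",
    "twister_structure",
    "triphosphorylation_structure",
    "toy_structure",
    "toy_two_module_structure",
]


def example_catalysts() -> list[ReactionParams]:
    """Four catalysts spanning the amplitude/rate trade-off.

    seq1 has the best fitness product A*k = 0.55 (wins at high
    stringency); seq3 has the best amplitude A = 0.7 (wins at
    saturation).
    """
    return [
        ReactionParams("seq1", A=0.55, k=1.0),
        ReactionParams("seq2", A=0.5, k=0.8),
        ReactionParams("seq3", A=0.7, k=0.6),
        ReactionParams("seq4", A=0.5, k=0.5),
    ]


def example_pool(
    artefact: bool = False,
    p0: float = 1e-14,
    Q: float = 0.2,
    kback: float = 0.001,
    artefact_Rart: float = 0.02,
) -> SpeciesPool:
    """The four example catalysts at frequency ``p0`` each, plus background.

    Set ``artefact=True`` to add a separation-step artefact with
    recovery probability ``artefact_Rart`` at frequency ``p0``.
    """
    catalysts = example_catalysts()
    return SpeciesPool(
        catalysts=catalysts,
        p0=[p0] * len(catalysts),
        Q=Q,
        kback=kback,
        artefact_Rart=artefact_Rart if artefact else None,
        artefact_p0=p0 if artefact else 0.0,
    )


def cofactor_pool(p0: float = 1e-14, Q: float = 0.2, kback: float = 0.001) -> CofactorPool:
    """Three-species counter-selection example.

    seq1 is constitutively active (k = 1), seq2 strictly
    cofactor-dependent (k = 0.8), seq3 leaky (k = 0.8 with cofactor,
    halved without); all amplitudes 0.5.
    """
    species = [
        CofactorSpecies("seq1", A=0.5, k=1.0, mode="constitutive"),
        CofactorSpecies("seq2", A=0.5, k=0.8, mode="dependent"),
        CofactorSpecies("seq3", A=0.5, k=0.8, mode="leaky"),
    ]
    return CofactorPool(species=species, p0=[p0] * len(species), Q=Q, kback=kback)


def constant_schedule(tau: float = 5.0) -> TauSchedule:
    return TauSchedule.constant(tau)


def stepped_schedule(
    tau0: float = 5.0, factor: float = 5.0, first_decay_round: int = 6
) -> TauSchedule:
    """tau = tau0 through round first_decay_round - 1, then divided by factor per round."""
    return TauSchedule.stepped(tau0, factor, first_decay_round)


def hammerhead_structure() -> StructureConstraint:
    """Hammerhead-motif counts: Lstr = 39, s = 13, b = 8, three modules."""
    return StructureConstraint(
        length=39,
        conserved={p: b for p, b in zip(
            [4, 5, 6, 7, 17, 18, 19, 20, 21, 30, 31, 32, 33],
            "CUGAUGAGGCGAA",
        )},
        pairs=(
            (1, 12), (2, 11), (3, 10),
            (14, 26), (15, 25), (16, 24),
            (27, 39), (28, 38),
        ),
        breaks=(13, 26),
        name="hammerhead-like",
    )


def twister_structure() -> StructureConstraint:
    """Twister-motif counts: Lstr = 54, s = 11, b = 17, three modules."""
    return StructureConstraint(
        length=54,
        conserved={p: b for p, b in zip(
            [7, 8, 9, 10, 25, 26, 27, 28, 42, 43, 44],
            "GUAAACUAAGC",
        )},
        pairs=(
            (1, 18), (2, 17), (3, 16), (4, 15), (5, 14), (6, 13),
            (19, 36), (20, 35), (21, 34), (22, 33), (23, 32), (24, 31),
            (37, 54), (38, 53), (39, 52), (40, 51), (41, 50),
        ),
        breaks=(18, 36),
        name="twister-like",
    )


def triphosphorylation_structure() -> StructureConstraint:
    """Self-triphosphorylation-motif counts: Lstr = 44, s = 13, b = 11, two modules,
    the first anchored at the 5' end (the reaction modifies the 5'-hydroxyl)."""
    return StructureConstraint(
        length=44,
        conserved={p: b for p, b in zip(
            [7, 8, 9, 10, 11, 12, 13, 28, 29, 30, 31, 32, 33],
            "GGAACUCAAGUGC",
        )},
        pairs=(
            (1, 22), (2, 21), (3, 20), (4, 19), (5, 18), (6, 17),
            (23, 44), (24, 43), (25, 42), (26, 41), (27, 40),
        ),
        breaks=(22,),
        anchored5=True,
        name="triphosphorylation-like",
    )


def toy_structure() -> StructureConstraint:
    """Tiny single-module structure (Lstr = 4, s = 1, b = 1) for exhaustive oracles."""
    return StructureConstraint(length=4, conserved={1: "G"}, pairs=((2, 4),), name="toy")


def toy_two_module_structure() -> StructureConstraint:
    """Tiny two-module structure (Lstr = 6, s = 2, b = 2) for exhaustive oracles."""
    return StructureConstraint(
        length=6,
        conserved={2: "A", 5: "C"},
        pairs=((1, 3), (4, 6)),
        breaks=(3,),
        name="toy-two-module",
    )
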