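"""Reference anthropoid study design: taxa, clades, sample sizes, chronogram.

The 27-species / 4-clade sampling scheme (platyrrhines, cercopithecoids,
hylobatids, hominids; 142 individuals in total) mirrors the comparative
design used in vestibular-shape studies of anthropoids.  The chronogram is
a FIXTURE: the topology follows the consensus molecular phylogeny of these
species, but node ages are nominal literature-informed values (a published
chronogram's exact ages are rarely distributed as text), so absolute dates
should not be quoted from it.  All ages in Ma; extant tips sit at age 0.
"""

from __future__ import annotations

from .trees import PhyloTree, attach_fossil_tip, parse_newick

__all__ = [
    "ANTHROPOID_NEWICK",
    "CLADE_OF_SPECIES",
    "SPECIMENS_PER_SPECIES",
    "CLADES",
    "anthropoid_tree",
    "species_groups",
    "add_reference_fossils",
]

#: Nominal time-calibrated topology over the 27 reference species.
ANTHROPOID_NEWICK = (
    "(((Alouatta_palliata:19,Ateles_geoffroyi:19):5,Cebus_apella:24):17,"
    "((((Colobus_guereza:9,Piliocolobus_badius:9):4,"
    "(Nasalis_larvatus:11,(Trachypithecus_cristatus:9,"
    "(Presbytis_hosei:3,Presbytis_rubicunda:3):6):2):2):5,"
    "((Macaca_fascicularis:10,((Mandrillus_sphinx:5.5,Cercocebus_galeritus:5.5):2.5,"
    "(Lophocebus_albigena:7,(Papio_anubis:4.5,Theropithecus_gelada:4.5):2.5):1):2):2,"
    "(Miopithecus_talapoin:9,(Cercopithecus_mitis:7.5,"
    "(Erythrocebus_patas:6,Chlorocebus_pygerythrus:6):1.5):1.5):3):6):12,"
    "((Hoolock_hoolock:8,(Hylobates_lar:7,Symphalangus_syndactylus:7):1):12,"
    "(Pongo_pygmaeus:16,(Gorilla_gorilla:9,((Pan_paniscus:2.5,Pan_troglodytes:2.5):4.5,"
    "Homo_sapiens:7):2):7):4):10):11);"
)

CLADES = ["Cercopithecoidea", "Hominidae", "Hylobatidae", "Platyrrhini"]

CLADE_OF_SPECIES = {
    "Alouatta_palliata": "Platyrrhini",
    "Ateles_geoffroyi": "Platyrrhini",
    "Cebus_apella": "Platyrrhini",
    "Cercocebus_galeritus": "Cercopithecoidea",
    "Cercopithecus_mitis": "Cercopithecoidea",
    "Chlorocebus_pygerythrus": "Cercopithecoidea",
    "Colobus_guereza": "Cercopithecoidea",
    "Erythrocebus_patas": "Cercopithecoidea",
    "Lophocebus_albigena": "Cercopithecoidea",
    "Macaca_fascicularis": "Cercopithecoidea",
    "Mandrillus_sphinx": "Cercopithecoidea",
    "Miopithecus_talapoin": "Cercopithecoidea",
    "Nasalis_larvatus": "Cercopithecoidea",
    "Papio_anubis": "Cercopithecoidea",
    "Piliocolobus_badius": "Cercopithecoidea",
    "Presbytis_hosei": "Cercopithecoidea",
    "Presbytis_rubicunda": "Cercopithecoidea",
    "Theropithecus_gelada": "Cercopithecoidea",
    "Trachypithecus_cristatus": "Cercopithecoidea",
    "Hoolock_hoolock": "Hylobatidae",
    "Hylobates_lar": "Hylobatidae",
    "Symphalangus_syndactylus": "Hylobatidae",
    "Gorilla_gorilla": "Hominidae",
    "Homo_sapiens": "Hominidae",
    "Pan_paniscus": "Hominidae",
    "Pan_troglodytes": "Hominidae",
    "Pongo_pygmaeus": "Hominidae",
}

#: Individuals per species in the reference design (142 crania in total).
SPECIMENS_PER_SPECIES = {
    species: 5 for species in CLADE_OF_SPECIES
} | {
    "Hoolock_hoolock": 6,
    "Hylobates_lar": 7,
    "Symphalangus_syndactylus": 4,
    "Gorilla_gorilla": 7,
    "Pan_troglodytes": 7,
    "Pongo_pygmaeus": 6,
}


def anthropoid_tree() -> PhyloTree:
    """The 27-species reference chronogram (extant taxa only)."""
    return parse_newick(ANTHROPOID_NEWICK)


def species_groups() -> dict[str, str]:
    """Species -> clade mapping for the reference design."""
    return dict(CLADE_OF_SPECIES)


def add_reference_fossils(tree: PhyloTree) -> PhyloTree:
    """Attach the two reference fossil lineages to a copy of the tree.

    *Oreopithecus* goes on the hominoid stem 1 Ma older than the
    hylobatid-hominid divergence, its tip at the midpoint (6.75 Ma) of its
    7.0-6.5 Ma last-occurrence interval.  *Australopithecus* is attached as
    sister to Homo sapiens with its tip at the 4.02 Ma first-appearance
    datum; its stem age (5.0 Ma) is nominal.
    """
    crown_hominoids = [
        "Hoolock_hoolock", "Hylobates_lar", "Symphalangus_syndactylus",
        "Pongo_pygmaeus", "Gorilla_gorilla", "Pan_paniscus",
        "Pan_troglodytes", "Homo_sapiens",
    ]
    hominoid_age = 20.0  # hylobatid-hominid split in the fixture
    out = attach_fossil_tip(
        tree, "Oreopithecus_bambolii",
        stem_attach_age=hominoid_age + 1.0, tip_age=6.75,
        sister=crown_hominoids,
    )
    out = attach_fossil_tip(
        out, "Australopithecus_sp",
        stem_attach_age=5.0, tip_age=4.02,
        sister="Homo_sapiens",
    )
    return out
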