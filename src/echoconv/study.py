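"""The 19-taxon study design: lineage groups, tree topology, comparisons.

Four echolocating lineage types are contrasted: constant-frequency (CF)
bats, frequency-modulated (FM) bats, tongue-click bats, and echolocating
toothed whales (TW). Nonecholocating pteropodid bats and the baleen whale
provide the phylogenetically matched controls.
"""

from __future__ import annotations

#: taxon labels per lineage; CF 3, FM 4, CLICK 2, NONECHO_BAT 2, TW 2,
#: BALEEN 1, OTHER 5 — 19 taxa in total
STUDY_LINEAGES: dict[str, tuple[str, ...]] = {
    "CF": ("Aselliscus_stoliczkanus", "Rhinolophus_sinicus", "Hipposideros_armiger"),
    "FM": ("Taphozous_melanopogon", "Myotis_davidii", "Myotis_brandtii", "Myotis_lucifugus"),
    "CLICK": ("Rousettus_leschenaultii", "Rousettus_aegyptiacus"),
    "NONECHO_BAT": ("Pteropus_vampyrus", "Pteropus_alecto"),
    "TW": ("Orcinus_orca", "Tursiops_truncatus"),
    "BALEEN": ("Balaenoptera_acutorostrata",),
    "OTHER": ("Homo_sapiens", "Mus_musculus", "Bos_taurus", "Equus_caballus",
              "Canis_lupus_familiaris"),
}

STUDY_TAXA: tuple[str, ...] = tuple(t for taxa in STUDY_LINEAGES.values() for t in taxa)

#: rooted binary topology consistent with the accepted mammal phylogeny:
#: rhinolophoid CF bats sister to pteropodids (click + nonecholocating fruit
#: bats) within Yinpterochiroptera, FM bats as Yangochiroptera, toothed
#: whales + baleen whale with Bos in Cetartiodactyla, and Homo/Mus outgroup.
STUDY_TOPOLOGY = (
    "((Homo_sapiens,Mus_musculus),"
    "((((Rhinolophus_sinicus,(Hipposideros_armiger,Aselliscus_stoliczkanus)),"
    "((Rousettus_leschenaultii,Rousettus_aegyptiacus),(Pteropus_vampyrus,Pteropus_alecto))),"
    "(Taphozous_melanopogon,(Myotis_davidii,(Myotis_brandtii,Myotis_lucifugus)))),"
    "((Bos_taurus,(Balaenoptera_acutorostrata,(Orcinus_orca,Tursiops_truncatus))),"
    "(Equus_caballus,Canis_lupus_familiaris))));"
)

#: representative extant species compared in each pairwise contrast
REPRESENTATIVES: dict[str, str] = {
    "CF": "Aselliscus_stoliczkanus",
    "FM": "Taphozous_melanopogon",
    "CLICK": "Rousettus_leschenaultii",
    "TW": "Tursiops_truncatus",
    "NONECHO_BAT": "Pteropus_vampyrus",
    "BALEEN": "Balaenoptera_acutorostrata",
}

#: the six echolocator pairwise comparisons
ECHOLOCATOR_PAIRS: tuple[tuple[str, str], ...] = (
    ("CF", "FM"),
    ("CF", "CLICK"),
    ("FM", "CLICK"),
    ("CF", "TW"),
    ("FM", "TW"),
    ("CLICK", "TW"),
)

#: the seven matched-control rows: (echolocating comparison, control
#: comparison); the click-bat-vs-toothed-whale contrast appears twice,
#: matched once against a bat control and once against a whale control
CONTROL_DESIGN: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("CF", "FM"), ("CF", "NONECHO_BAT")),
    (("CF", "CLICK"), ("CF", "NONECHO_BAT")),
    (("FM", "CLICK"), ("FM", "NONECHO_BAT")),
    (("CF", "TW"), ("CF", "BALEEN")),
    (("FM", "TW"), ("FM", "BALEEN")),
    (("CLICK", "TW"), ("CLICK", "BALEEN")),
    (("CLICK", "TW"), ("NONECHO_BAT", "TW")),
)


def pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]} vs. {pair[1]}"


def representative_pair(pair: tuple[str, str]) -> tuple[str, str]:
    """Map a lineage pair to its representative extant taxon pair."""
    return REPRESENTATIVES[pair[0]], REPRESENTATIVES[pair[1]]
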