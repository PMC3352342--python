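"""Packaged study inputs.

The co-divergence analysis runs on three fixed inputs shipped with the
package:

* the strain-to-vector association table for the 14 well-characterized
  insect-specific flavivirus strains (plus DENV1) tested for co-divergence;
* the NS5 insect-specific virus topology restricted to those 14 strains;
* a mosquito host topology assembled from the morphological and molecular
  literature (no single published phylogeny covers all the genera involved):
  the two *Culex* species are sisters with *Cx. tritaeniorhynchus* sister to
  the pair; *Mansonia* and the aedines (*Neomelaniconion*, *Stegomyia*) form
  the other clade, with *Neomelaniconion* closer to *Stegomyia* than to
  *Culex*.

*Cx. tritaeniorhynchus* appears in the host tree although no packaged strain
maps to it: an unmapped host leaf cannot change codivergence, duplication or
switch counts, only losses.

The conserved 14-residue fusion-peptide motifs of the E protein are also
packaged here ('X' is a wildcard position; the traditional-flavivirus motif
ends in G or H).
"""

from __future__ import annotations

from importlib import resources

from .screens import MotifProfile
from .trees import AssociationMap, PhyloTree, build_host_tree, load_associations, parse_newick

__all__ = [
    "insect_specific_associations",
    "ns5_virus_tree",
    "mosquito_host_tree",
    "DEFAULT_HOST_SPEC",
    "FUSION_PEPTIDE_MOTIFS",
    "CULEX_HOSTS",
    "STEGOMYIA_GROUP_HOSTS",
    "culex_group",
    "stegomyia_group",
]

DEFAULT_HOST_SPEC = (
    (
        ("Culex_pipiens", "Culex_quinquefasciatus"),
        "Culex_tritaeniorhynchus",
    ),
    (
        "Mansonia_africana",
        (
            "Neomelaniconion_mcintoshi",
            ("Stegomyia_aegypti", "Stegomyia_albopicta"),
        ),
    ),
)

CULEX_HOSTS = frozenset(
    {"Culex_pipiens", "Culex_quinquefasciatus", "Culex_tritaeniorhynchus"}
)

# KRV's vector Neomelaniconion mcintoshi is an aedine related more closely to
# Stegomyia than to Culex; the Stegomyia-side subgroup analysis therefore
# covers the CFAV+AeFV+KRV clade.  DENV1 (not insect-specific) is excluded
# from both subgroup analyses.
STEGOMYIA_GROUP_HOSTS = frozenset(
    {"Stegomyia_aegypti", "Stegomyia_albopicta", "Neomelaniconion_mcintoshi"}
)

FUSION_PEPTIDE_MOTIFS = (
    MotifProfile(name="KRV_AeFV", pattern="NRGWGTGCFEWGLG", source_group="KRV/AeFV"),
    MotifProfile(name="NAKV", pattern="NRGWGTGCLEWGLG", source_group="NAKV"),
    MotifProfile(name="CFAV_CxFV", pattern="NRGWGTGCFKWGLG", source_group="CFAV/CxFV"),
    MotifProfile(
        name="traditional",
        pattern="DRGWXXGCXXFGK[GH]",
        source_group="traditional flaviviruses",
    ),
)


def _data_text(name: str) -> str:
    return resources.files("flavicophy.data").joinpath(name).read_text()


def insect_specific_associations() -> AssociationMap:
    """The packaged 14-row strain-to-vector association table."""
    import io

    return load_associations(io.StringIO(_data_text("associations.tsv")))


def ns5_virus_tree() -> PhyloTree:
    """NS5 insect-specific virus topology restricted to the 14 tested strains."""
    return parse_newick(_data_text("virus_ns5.nwk"))


def mosquito_host_tree() -> PhyloTree:
    """The fixed mosquito host topology (see module docstring)."""
    return build_host_tree(DEFAULT_HOST_SPEC)


def _group(assoc: AssociationMap, hosts: frozenset, exclude=("DENV1",)) -> list[str]:
    return [
        v for v, h in assoc.records if h in hosts and v not in exclude
    ]


def culex_group(assoc: AssociationMap | None = None) -> list[str]:
    """Strain labels of the Culex-associated insect-specific viruses."""
    return _group(assoc or insect_specific_associations(), CULEX_HOSTS)


def stegomyia_group(assoc: AssociationMap | None = None) -> list[str]:
    """Strain labels of the Stegomyia-side (aedine-associated) viruses."""
    return _group(assoc or insect_specific_associations(), STEGOMYIA_GROUP_HOSTS)
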