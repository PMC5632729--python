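import textwrap

import pytest

from plastcomp import synthetic as syn
from plastcomp.synthetic import PlantedRepeatSpec, PlantedSSRSpec, SimConfig

# A hand-written three-gene GenBank record (121 bp) with one origin-spanning
# CDS and one pseudogene; coordinates below are GenBank 1-based inclusive.
THREE_GENE_GENBANK = textwrap.dedent("""\
    LOCUS       TESTREC                  121 bp    DNA     circular PLN 01-JAN-2020
    DEFINITION  synthetic three-gene test record.
    ACCESSION   TESTREC
    VERSION     TESTREC.1
    FEATURES             Location/Qualifiers
         source          1..121
                         /organism="synthetic construct"
         gene            5..22
                         /gene="geneA"
         CDS             5..22
                         /gene="geneA"
         gene            complement(31..45)
                         /gene="trnX"
         tRNA            complement(31..45)
                         /gene="trnX"
         gene            61..75
                         /gene="psbZ"
                         /pseudo
         gene            join(112..121,1..2)
                         /gene="wrapY"
         CDS             join(112..121,1..2)
                         /gene="wrapY"
    ORIGIN
            1 gatccgatta cgatcgtacg tagctagcta catgcatgca tgcaagctta gctagcatcg
           61 atgcatgcat cgatcatgca tcgatcgtag ctagcatcgt acgtacgatc gatcgatcga
          121 t
    //
    """)


@pytest.fixture()
def three_gene_gb(tmp_path):
    path = tmp_path / "three_gene.gb"
    path.write_text(THREE_GENE_GENBANK)
    return path


@pytest.fixture(scope="session")
def compact_cfg() -> SimConfig:
    return SimConfig.compact(
        seed=11,
        planted_ssrs=(
            PlantedSSRSpec("A", 9),
            PlantedSSRSpec("AT", 6, "SSC"),
            PlantedSSRSpec("AAG", 4),
        ),
        planted_repeats=(
            PlantedRepeatSpec("forward", 40, 0),
            PlantedRepeatSpec("palindromic", 35, 2),
            PlantedRepeatSpec("reverse", 33, 1, "SSC"),
        ),
    )


@pytest.fixture(scope="session")
def ancestor(compact_cfg):
    return syn.generate_ancestor(compact_cfg)


@pytest.fixture(scope="session")
def evolved_pair(ancestor):
    plastome, truth = ancestor
    d1, d2, ledger = syn.evolve_pair(plastome, truth)
    return d1, d2, ledger, truth
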