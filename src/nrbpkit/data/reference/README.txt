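Reference sequences
===================

The worked pairwise-identity example compares the canonical human NRBP1 and
NRBP2 proteins.  These UniProt sequences (NRBP1: Q9UHY1; NRBP2: Q9NSY0) are
not redistributed with the package.  To enable the real-sequence check, place
the two single-record FASTA files here:

    NRBP1_HUMAN.fasta
    NRBP2_HUMAN.fasta

e.g. downloaded from https://rest.uniprot.org/uniprotkb/Q9UHY1.fasta and
https://rest.uniprot.org/uniprotkb/Q9NSY0.fasta.

Without them, functions that need the real pair report that the files are
absent; all synthetic-data functionality is unaffected.
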