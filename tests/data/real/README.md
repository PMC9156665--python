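# Real-genome inputs (not shipped)

The acceptance tests for genome-wide targetability and worked-example
recovery run against published RefSeq genomes that are too large to ship
with the repository and must be fetched on a machine with network access:

- `NC_002947.gb` — *Pseudomonas putida* KT2440 chromosome (RefSeq
  NC_002947, GenBank flat file with CDS features, ~6 MB)
- `NC_008463.gb` — *Pseudomonas aeruginosa* UCBPP-PA14 chromosome (RefSeq
  NC_008463.1, GenBank flat file with CDS features)

Place the files in this directory under exactly those names, e.g. with the
NCBI datasets/efetch tooling:

    efetch -db nuccore -id NC_002947 -format gbwithparts > NC_002947.gb
    efetch -db nuccore -id NC_008463.1 -format gbwithparts > NC_008463.gb

When a file is missing, the corresponding acceptance tests fail with a
message pointing here; they are intentionally not skipped.
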