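# Reference accession records

The published-value comparisons in `tests/test_acceptance.py` read annotated
plastome records from this directory:

- `LC199394.gb` — *Apostasia wallichii* plastome
- `LC199503.gb` — *Neuwiedia singapureana* plastome
- `NC_030722.gb` — *Apostasia odorata* plastome

These are third-party GenBank records (~150-165 kb each) and are not
redistributed with the package. Fetch them once with network access, e.g.:

```sh
for acc in LC199394 LC199503 NC_030722; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gbwithparts&retmode=text" \
    > data/accessions/${acc}.gb
done
```

Without these files the corresponding tests fail with a message pointing
here; every other test runs on generated data alone.
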