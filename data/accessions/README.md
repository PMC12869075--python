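# Accession inputs (not redistributed)

The locus-level reproduction tests in `tests/test_acceptance.py` and the
`ncs-atlas reproduce` workflow on the real human rDNA repeat expect the
following files in this directory. They are third-party sequence records
and a published coverage track, so they are not shipped with the package;
fetch them once on a machine with network access:

```sh
# human rDNA repeat backbone (44,838 nt)
curl -o KY962518.1.fasta \
  'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=KY962518.1&rettype=fasta&retmode=text'

# comparison transcription units
for acc in KX061890 BK000964 KT445934; do
  curl -o ${acc}.fasta \
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text"
done
```

`KY962518.1.regions.bed` is a BED4 annotation of the backbone regions
(5ETS, 18S, ITS1, 5.8S, ITS2, 28S, 3ETS, IGS; 0-based half-open
coordinates on the deposited strand) derived from the accession's
GenBank feature table; the pipeline treats it strictly as input.

`polr1a.bedgraph` is the POLR1A ChIP-seq coverage track from
github.com/vikramparalkar/rDNA-Mapping-Genomes, converted from bigWig
with `bigWigToBedGraph` (or pyBigWig) against the reconstructed locus
coordinates.
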