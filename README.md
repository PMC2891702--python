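# spliceseek

Combinatorial screening of proteasome-generated spliced peptides (PSP) from
polypeptide digests. From one or two substrate sequences, `spliceseek`:

1. **enumerates** every cleavage product (contiguous fragment, PCP) and every
   ordered ligation of two fragments (splice product, PSP), classifying each
   pair as *cis-normal* (substrate order, gap ≥ 1), *cis-reverse*
   (second fragment upstream of the first) or *trans* (overlapping
   fragments, self-pairs, or two substrate molecules);
2. **builds a theoretical m/z database** — neutral monoisotopic (or average)
   masses, protonated m/z for charges 1–3, greedy clustering of m/z values
   into groups of span ≤ 0.2 Da with mean representatives, and a searchable
   FASTA export for external MS/MS engines;
3. **screens** the clusters against centroided MS1 peak lists acquired at a
   series of digestion times: m/z matching (±0.5 Da), XIC peak detection
   (apex/median S/N > 2), and kinetic filtering (t = 0 intensity below 1e7,
   monotone rise to t_max, optional monotone re-entry decline);
4. **emits a precursor inclusion list** for targeted MS/MS: candidates are
   grouped by t_max and split into balanced subgroups of at most 15.

A synthetic digest simulator with planted product kinetics, contaminants and
decoys (plus a ground-truth manifest) makes the full pipeline testable
offline, and supports heavy-isotope substrate analogues (e.g. ¹³C₆-Lys,
¹⁵N-Leu) for diagnosing trans splicing via the four light/heavy variants.

## CLI

```bash
# all splice products of a 4-mer
echo "tiny ACDE" > sub.txt
spliceseek enumerate sub.txt -o psp.tsv

# theoretical database (TSV + FASTA + stats) for a 13-mer substrate
echo "gp100_40-52 RTKAWNRQLYPEW" > sub13.txt
spliceseek build-db sub13.txt -o db/

# synthetic time-course with 5 planted products and 50 decoys
spliceseek simulate sub13.txt -o sim/ --n-planted 5 --n-decoys 50 --seed 1

# full screen: database -> match -> kinetics -> inclusion list
spliceseek pipeline sub13.txt -o run/ \
    --peaks sim/peaks_t0000000.0min.csv --peaks sim/peaks_t0000020.0min.csv \
    --peaks sim/peaks_t0000060.0min.csv --peaks sim/peaks_t0000180.0min.csv \
    --peaks sim/peaks_t0000360.0min.csv --peaks sim/peaks_t0000720.0min.csv \
    --peaks sim/peaks_t0001440.0min.csv
```

Stepwise commands (`match`, `kinetics`, `inclusion`, `export-fasta`) operate
on the TSV/CSV artifacts; a YAML config (`--config`) can set `l_ext`,
`cluster_width`, `charges`, `mz_tolerance`, `delta`, `max_t0_intensity`,
`allow_reentry`, `d_max`. Substrates longer than 60 residues are refused
unless `--allow-long` is given (the product space grows combinatorially).

## Library sketch

```python
from spliceseek import (BUNDLED_SUBSTRATES, DbParams, FilterParams,
                        build_database, end_to_end_fixture, screen_peaklists)
from spliceseek.io import concat_peaklists

sub = BUNDLED_SUBSTRATES["gp100_40-52"]
cfg, db, peaklists, truth = end_to_end_fixture(sub, n_planted=6, n_decoys=100, seed=1)
result = screen_peaklists(db, concat_peaklists(peaklists.values()), FilterParams())
print(result.step_counts)
```
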