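# tgxlink

A library and CLI that identifies transglutaminase (TG) Lys–Gln isopeptide
cross-linked peptide pairs from tandem-MS peak lists of digested proteins.

The TG cross-link condenses a glutamine side-chain amide with a lysine
ε-amine, so a cross-linked pair weighs the sum of its two peptides minus one
ammonia (−17.03 Da). `tgxlink` performs:

* in silico tryptic digestion with missed cleavages and length bounds
  (reversed-sequence decoys included),
* enumeration of K↔Q cross-linkable peptide pairs within a ppm precursor
  tolerance, with fixed/variable modification expansion,
* branched b/y fragment prediction (fragments spanning the linked site carry
  the whole partner chain as a fixed mass),
* tolerance-based peak matching and a four-score match statistic family
  (descriptive `score`, binomial-tail `pp`, matched-abundance `pp2`,
  sequence-tag `pp_tag`), combined per site into an overall score,
* site acceptance (overall ≥ 15 **and** ≥ 2 passing spectra by default),
  target–decoy FDR q-values and a Q×K heat map,
* a seeded synthetic CID spectrum simulator so the whole pipeline is
  testable without any raw data download.

## CLI

```sh
# masses and m/z table of a cross-linked pair (Lys donor first)
tgxlink mass EGGKGPR SQDGGR

# tryptic digest / model-pair design from FASTA
tgxlink digest proteins.fasta
tgxlink design proteins.fasta

# generate a seeded benchmark (MGF + ground-truth TSV); with no FASTA a
# built-in collagen-like model protein is used
tgxlink simulate proteins.fasta --out-dir bench --seed 7

# full search: results.tsv, heatmap.tsv, manifest.json
tgxlink search proteins.fasta bench/benchmark.mgf --out-dir out --seed 7
```

Search settings can come from a YAML config (`--config search.yaml`) whose
keys mirror `tgxlink.pipeline.Config` (e.g. `precursor_tol_ppm: 20`,
`fragment_tol_da: 0.8`, `max_missed: 2`, `min_len: 6`, `max_len: 40`,
`overall_threshold: 15`, `min_spectra: 2`, `var_mods: [oxidation,
deamidation]`, `fixed_mods: [carbamidomethyl]`); command-line flags win over
the file.

Cross-linked residues are marked `$1` in result rows (e.g. `EGGK$1GPR`) and
oxidized methionines render as `oxM`.

## Library

```python
from tgxlink.chem import Peptide, make_pair, mz
from tgxlink.pipeline import Config, run_search
from tgxlink.synthetic import SimParams, generate_benchmark

pair = make_pair(Peptide("EGGKGPR", "p", 1, 7), Peptide("SQDGGR", "p", 1, 6), 4, 2)
print(round(pair.neutral_mass, 2), round(mz(pair.neutral_mass, 2), 2))
# 1300.61 651.31
```

## Notes

* Sequential Lys-C + trypsin digestion is modelled as plain trypsin: the
  trypsin cleavage set (K, R) contains Lys-C's (K), so the final peptide set
  is governed by the trypsin rule.
* The missed cleavage at a cross-linked K does not count toward the
  missed-cleavage budget (the cross-link blocks cleavage there).
* `pp`/`pp2`/`pp_tag`/overall are documented surrogate statistics (binomial
  tail, Monte-Carlo abundance null with a normal-tail refinement, tag-run
  tail, mean-sum combination); their thresholds are qualitative anchors, not
  bit-compatible with any external engine.
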