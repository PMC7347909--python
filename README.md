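# hgscan

Detection and quantification of the microbial mercury-methylation marker
genes *hgcA* and *hgcB* in short-read metagenomes, with the supporting
statistics used in water-column survey studies: single-copy-gene
normalization, KEGG-style module completion ratios, and rank correlation of
marker abundance against mercury chemistry.

Everything runs desk-scale on synthetic data: the package ships its own
reference-family generator, community/read simulator and analytic recovery
oracle, so the whole pipeline is testable end to end without external
databases or sequencing archives.

## What it does

* **Synthetic references and libraries** (`hgscan.synthetic`) — seeded
  generation of protein reference families (hgcA with its cap-helix motif,
  hgcB with two ferredoxin motifs, recA, an unrelated decoy), benchmark
  communities with known hgcA:recA copy ratios, and 2×250 bp paired-end
  libraries with realistic insert sizes, base errors and quality dropout.
* **Read preprocessing** (`hgscan.readprep`) — adapter trimming, overlap
  merging with per-base consensus (quality-weighted; ties become `N`), and
  mean-quality/length filtering.
* **Marker search** (`hgscan.orf`, `hgscan.profile`) — six-frame ORF calling
  (translation table 11, edge-partial ORFs allowed) and a from-scratch
  profile model per family: log-odds match emissions over alignment columns,
  banded local Viterbi alignment with affine gaps, k-mer prefiltering, and
  Gumbel-calibrated E-values.
* **Motif validation** (`hgscan.motifs`, `hgscan.validate`) — hits only count
  when the catalytic motif is confirmed on the read itself: the cap-helix
  Cys aligned to reference column 93 for hgcA, two non-overlapping
  `CxxCxxCxxxC` motifs for hgcB. Rejections carry explicit reasons.
* **Quantification** (`hgscan.quantify`) — fragment-level dedup counting,
  recA-relative abundance (undefined, not zero, when recA is absent), and an
  exact analytic oracle for expected recovery on simulated communities.
* **Pathway modules** (`hgscan.modules`) — module completion ratios over KO
  count tables; the 10-KO reductive acetyl-CoA pathway table ships as a
  packaged fixture.
* **Mercury statistics** (`hgscan.hgstats`) — pg/L→pM conversion, "ND"
  censoring, Spearman correlation with exact permutation p-values below
  n = 10, and the marker × mercury-species correlation table.
* **Pipeline + CLI** (`hgscan.pipeline`, `hgscan` command) — one-call sample
  processing and a simulated two-station depth-profile study.

## Quick start

```sh
# simulate a benchmark library with a 1% hgcA-carrier fraction
hgscan simulate --ratio 0.01 --n-pairs 10000 --seed 0 --out-prefix lib

# run the full pipeline: QC -> ORFs -> profile search -> validation -> counts
hgscan quantify lib_R1.fastq lib_R2.fastq --out abundance.tsv

# module completion ratios of the packaged acetyl-CoA table
hgscan mcr

# simulated depth-profile study + marker x mercury correlations
hgscan study --seed 0 --n-pairs 20000 --out correlations.tsv
```

Python API:

```python
from hgscan import (default_families, build_profiles, recovery_community,
                    simulate_reads, run_sample, SimulationConfig)

families = default_families(seed=0)
profiles = build_profiles(families)
community = recovery_community(0.01, families, seed=0)
sim = simulate_reads(community, SimulationConfig(n_pairs=10000, seed=0))
result = run_sample(sim.pairs, profiles, sample_id="demo")
print(result.counts, result.abundance["hgcA"].rel_pct)
```

## Testing

```sh
python -m pytest -q tests/
```

The suite includes property-based tests against brute-force oracles (motif
scanning, ORF calling, read merging, exact Spearman p-values), an
independent profile-search cross-check against pyhmmer, and stochastic
recovery tests against the analytic detection oracle. `tests/test_acceptance.py`
holds one test per acceptance criterion; `scripts/acceptance.py` writes the
target values as JSON:

```sh
python scripts/acceptance.py --seed 0 --out results/acceptance.json
```

See `docs/methods.md` for the algorithmic conventions and their rationale.
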