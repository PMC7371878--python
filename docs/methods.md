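# Methods

## Model and procedure

The unit of analysis is a cohort of `N` undirected, unweighted graphs
`G_i(V, E_i)` on one shared labelled vertex set `V`, plus an integer score
per subject.  For a target specification `u` (one node, or two nodes whose
adjacency lists are unioned), subject `i` contributes the neighbor set
`Γ_i(u)`, minus the targets themselves and any explicitly excluded labels —
a node is never its own candidate neighbor.  The analysis asks which
subsets `W` of the candidate universe are *frequent* (`W ⊆ Γ_i(u)` for at
least `⌈tN⌉` subjects) within each score group, and which of those differ
in frequency between the groups.

Four steps, each an importable module:

1. **Phenotype split** (`fnnm.phenotype`): high = score ≥ cutoff, low =
   score < cutoff.  A `"median"` cutoff resolves to the sample median
   rounded up to an attained integer score, which reproduces the standard
   brackets for the two bundled tests (Penn Matrix: low 0–16 / high 17–24;
   Penn Word Memory: low 0–35 / high 36–40).  The median score itself lands
   in the high group.  Missing scores drop a subject from that test only.
2. **Mining** (`fnnm.mining`): levelwise apriori over the binary
   subjects × candidates membership matrix.  Size-(m+1) candidates are
   joins of frequent size-m sets sharing an (m−1)-prefix, pruned when any
   m-subset is infrequent; supports are exact row counts (boolean AND of
   cached row masks), never sampled.  The miner is validated against an
   independent exhaustive enumerator on randomized tables.
3. **Comparison** (`fnnm.comparison`): the candidate family is the union
   of the sets frequent in the high group and those frequent in the low
   group, all sizes pooled into one family per (target, test) analysis.
   Each candidate's 2×2 table is tested with the uncorrected Pearson
   chi-square (1 df); a zero presence/absence margin yields χ² = 0, p = 1.
   Holm–Bonferroni step-down over the family controls the family-wise
   error rate at α.
4. **Reporting** (`fnnm.pipeline`): per-group frequent-set counts by size,
   the significant count, and its good/bad decomposition; full per-set
   listings sorted by (size, members); run metadata with realized group
   sizes.  Output inventories and bytes are deterministic given inputs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_fraction` | 0.8 (0.9 for the union target) | minimum within-group support as a fraction of that group's N; the support bound is `⌈tN⌉`, the smallest k with k/N ≥ t |
| `max_size` | 4 | largest mined set size; the candidate space above 4 is astronomically large and frequency there adds little interpretive value |
| `alpha` | 0.01 | family-wise significance bound after Holm correction |
| `cutoff` | `"median"` | integer score cutoff; high = score ≥ cutoff |
| `cohort_wide_threshold` | off | derive one support count from the pooled N instead of per-group N (sensitivity variant) |
| `yates` | off | continuity-corrected chi-square (sensitivity variant) |

Per-group thresholds are the default because the method reports each
group's frequent-set counts separately; the pooled variant is retained as
a config flag for sensitivity analysis.  The Holm family spans one
(target, test) analysis; analyses for different targets or tests are
corrected independently.

## Synthetic cohort generator

`fnnm.synthetic` emulates the statistical skeleton of a connectome cohort:

- a 463-label universe in parcellation naming style (cortical
  `lh./rh.<region>_<k>` subdivisions plus subcortical structures), with
  cohort defaults of 207 + 206 subjects;
- per-candidate baseline inclusion probabilities drawn once from
  U(0.05, 0.6), so ordinary candidates sit well below an 80 % threshold
  and frequency structure must be planted deliberately;
- planted sets inserted **atomically**: per subject one Bernoulli draw at
  the group's probability puts all members into `Γ` together.  Planted
  members are withheld from the baseline draws, so a planted set's
  support is exactly its Bernoulli count and recovery power is
  analyzable in closed form.  `baseline_on_planted_members=True` restores
  baseline noise on top for harder tests;
- scores drawn uniformly on [cutoff, max] for the high group and
  [min, cutoff−1] for the low group, so the generating labels are
  recovered exactly by the split;
- background Bernoulli(0.02) edges among non-target node pairs, giving
  files of realistic size (~2–3 thousand edges) without touching any
  neighbor set; with two targets the inter-target edge is always present
  (its analogue in real cohorts is near-universal);
- one integer seed drives separate membership, score, and per-subject
  background substreams via a spawned SeedSequence tree; outputs are
  byte-identical across runs.

What the generator does **not** emulate: anatomical geometry, edge
weights, hemispheric symmetry, or correlation between candidate nodes
beyond planted co-occurrence.  Passing tests therefore demonstrate the
pipeline's correctness and calibration under independence, not the
discovery power to be expected on real cohorts, where neighbor
co-occurrence is correlated and group assignment is noisy.

## Numerical and design choices

- `⌈tN⌉` is computed with a 1e-12 guard against binary-float artifacts
  (e.g. 0.8 × 5 evaluating to 4.0000000000000002).
- Mining output order is (size, lexicographic members); ties cannot occur.
- The empty set is never reported (supports would be trivially N).
- Candidate families are tested in full: no minimum-expected-count filter
  is applied, because candidates are ≥ 80 % frequent in at least one group
  and their cells are large by construction; a warning is logged if an
  expected count falls below 5 (possible when group sizes are very
  unbalanced).
- Equal group proportions give χ² = 0, so a significant result always has
  a well-defined direction; this is asserted, not assumed.
- Subjects missing the target node raise an error instead of contributing
  an empty neighborhood, which would silently deflate supports.
- Graph ingestion deduplicates reversed edge orientations, drops
  self-loops with a warning, ignores weight columns, and auto-detects
  CSV/TSV delimiters and header rows; GraphML is accepted as an
  alternative container.

## Calibration and recovery checks

The acceptance suite establishes, by simulation at one-CPU scale:

- **Oracle equivalence**: apriori = exhaustive enumeration (sets and
  supports) on 200 random tables across thresholds 0.5–1.0.
- **FWER**: on 500 null cohorts (100 subjects/group, 30 candidates at 90 %
  baseline inclusion, threshold 0.8, sets up to size 2), the fraction of
  replicates with any Holm rejection stays ≤ 0.03 — the nominal 0.01
  guarantee plus Monte-Carlo slack.  Size-2 mining keeps the null family
  (~400–500 candidate sets) representative while the 500 replicates stay
  cheap; the guarantee itself is size-agnostic.
- **Recovery**: a pair planted at 90 % (high) vs 60 % (low) inclusion with
  200 subjects/group is mined and flagged significant-good in ≥ 90 % of
  replicates, and the direction flips when the probabilities are swapped.
- **Scale**: the full pipeline (generation, file round-trip, left + right
  + union analyses at thresholds 0.8/0.8/0.9, max size 4) on 414 subjects
  × 463 nodes completes in about a minute.

`scripts/acceptance.py` recomputes all of these from scratch at reduced
replicate counts (50 recovery / 200 null replicates, chosen to keep the
script at a few minutes) and writes them as JSON.

## Limitations

- Only undirected, unweighted graphs; weights in input files are ignored.
- The chi-square test assumes large cells; with very small groups a Fisher
  exact test would be preferable and is deliberately not provided.
- Holm correction treats each (target, test) analysis as its own family;
  running many analyses multiplies the cohort-level error accordingly.
- Mining cost grows with the number of candidates near the threshold; at
  an 80 % threshold on realistic cohorts the frequent lattice is small,
  but low thresholds (< 0.5) on dense tables can be expensive.
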