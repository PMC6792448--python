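# Methods

## Model

Each Pfam domain is treated as a binary character on a fixed rooted
species tree. Under Dollo parsimony a character arises exactly once and
every loss is irreversible: no lineage regains a domain its ancestor
lost. Given the set of possessing tips, the minimal-loss history is
unique: the gain sits at the MRCA of the possessing tips (the tip
itself for a single-taxon domain), a node below the gain is present iff
its clade contains at least one possessing tip, and one loss event is
charged to the branch entering the topmost absent node of each maximal
lost subtree. Uniqueness follows because the gain must be an ancestor
of every possessing tip (anything lower needs a second gain) and each
step rootward of the MRCA adds at least one absent child subtree, hence
at least one extra loss. The package asserts this by exhaustive
enumeration (`brute_force_oracle`) over all single-gain internal-state
assignments on every rooted binary topology with up to 6 tips.

Reconstruction is topology-only: branch lengths and support values are
parsed and re-serialised but never interpreted. Polytomies are retained;
each child of a polytomy is evaluated independently for loss events.
Copy numbers are kept in the matrix for reporting, but reconstruction
consumes the binary presence view — duplications are out of scope.
Domains present in no tip are skipped and reported, since Dollo has no
gain to place. The tree's root is the analysis root; domains gained
there are reported as "present at root" and not dated further.

Per-node tallies obey the conservation identity
`content(n) = content(parent) − losses(n) + gains(n)` with
`content(root) = gains(root)`; `GainLossSummary.check_conservation`
verifies it after every reconstruction, and it reproduces the published
metazoan-stem arithmetic 5715 − 399 + 181 = 5497 used as a printed-scale
sanity check.

## Parameters and conventions

| parameter | default | meaning |
|---|---|---|
| prokaryotic threshold | 0.95 | domains with prokaryotic prevalence ≥ threshold are removed (boundary inclusive, "95 % or more"); domains missing from the table are kept with a warning |
| retention threshold, strict | 0.70 | "over 70 %": counted when p > 0.70 |
| retention threshold, non-strict | 0.50 | "half or more": counted when p ≥ 0.50 |
| pfam_fraction | 0.70 | fraction of true proteins expected to carry ≥ 1 Pfam domain; from the two reference choanoflagellate proteomes, configurable per clade |
| significance | flag = 1 | pfam_scan hits are kept when their significance flag is set; an optional E-value ceiling can be added |

Retention is membership in the post-filter presence matrix, not
re-annotation. Incomplete genomes are handled by an exclusion list and
enter neither k nor n. The median of an even-sized list is the mean of
the central pair. Completeness percentages are consumed on the 0–100
scale (values above 100 are rejected, guarding against mixed scales);
"complete + fragmented" pooling is done upstream by the user. Gene
counts are rounded half away from zero; genome sizes are computed at
full precision and displayed at 0.1 Mb.

Internal nodes without Newick labels get stable preorder ids
(`N0 = root, N1, ...`) so outputs are reproducible run to run; original
labels are preserved and shown alongside. Retention tables sort by p
descending with ties broken by domain name; matrix columns sort domains
lexicographically so assembly is independent of input record order.

## Synthetic data

`simulate_yule_tree` grows a pure-birth topology by splitting a
uniformly chosen tip until the requested size; no branch lengths are
assigned (reconstruction ignores them). `simulate_domain_evolution`
places each domain's gain uniformly over nodes (or on an explicit node
list) and walks the subtree in pre-order, losing the domain on each
branch with a constant probability — irreversibility is structural,
because traversal stops at a lost branch. Domains that survive in no
tip are re-drawn and the redraw count reported, so the ascertainment
induced by conditioning on survival is visible. Decoy domains are
flagged and given prokaryotic prevalence 0.96 (others 0.10) in the
emitted table. The HGT violation mode adds, with the configured
probability, a second independent gain in a clade disjoint from the
first, deliberately breaking the single-origin assumption: for such
domains with survivors from both origins, the single-gain
reconstruction is pulled rootward to a common ancestor of both true
gains — the package asserts exactly that directional bias, not a loss
over-count, since loss counts under violation are not monotone.

The generator emulates presence/absence dynamics only. It does not
model copy-number change, branch-length-dependent loss rates,
annotation error, or the correlated missingness of genuinely incomplete
assemblies — so passing recovery tests show the reconstruction is
correct under its own assumptions (and conservatively biased under
losses: inferred gains sit at or below the true origin, inferred loss
counts never exceed the true event count), not that real data meet
those assumptions.

## Problem sizes

Defaults were chosen at the scale a desk analysis needs: exhaustive
oracle parity over all rooted binary topologies with ≤ 6 tips and all
non-empty patterns (63 039 cases); recovery over 10 000 simulated
domains on a 30-tip tree at loss probabilities 0 and 0.2; filter and
retention checks on 200-domain simulations. Each finishes in seconds.

## Known limitations

- Dollo parsimony under-counts events when a domain truly originated
  twice (horizontal transfer); the violation mode quantifies the
  direction of that bias but the pipeline does not detect HGT.
- The genome-size extrapolation assumes benchmark genes are distributed
  homogeneously and pools complete with fragmented hits; the emitted
  report repeats these caveats. Published rounded inputs reproduce the
  UC4 estimate exactly (52.5 Mb) but give 29.9 Mb for UC1 against a
  printed 29.4 Mb — unrounded completeness values were presumably used
  upstream; the package computes from its stated inputs.
- Probabilistic birth–death gain/loss models (maximum-likelihood family
  content reconstruction), Wagner parsimony and gene-tree reconciliation
  are out of scope.
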