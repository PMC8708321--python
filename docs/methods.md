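# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs.

## Curation into free form and in-blood form

The free form of a compound is its neutral parent: the largest fragment of
a multi-fragment SMILES (most heavy atoms, ties by carbon count then
lexicographically smallest canonical SMILES), with protonated amines
returned to free bases and carboxylate/phenolate/thiolate/alkoxide anions
protonated. Quaternary ammonium nitrogens carry no proton and remain
cationic; a molecule whose neutralized form fails valence sanitization is
returned unchanged rather than corrupted. Identity for deduplication is the
canonical SMILES of this free form, so different salts of one drug collide.
Within an identical-structure group, records agreeing on the label keep the
numerically smallest identifier; groups with conflicting labels are removed
entirely, since a contradicted label cannot train anything. Records whose
SMILES cannot be parsed pass through unmodified and are flagged in the
curation report — structure fixes are data, supplied as a two-column
`num,smiles` patch file, not code.

The in-blood form applies an ordered rule table (packaged as editable YAML:
SMARTS pattern, site index, pKa, action). A deprotonation rule fires only
when pKa < pH − margin and a protonation rule only when pKa > pH + margin,
with pH 7.4 and margin 1.0 log unit: a site within one log unit of blood pH
is mixed-species, and the single-dominant-species convention keeps it
neutral. First match wins per atom. Amino acids get both an anionic
carboxylate and a protonated amine, i.e. the zwitterion. The default pKa
values are general textbook values per functional-group class (carboxylic
4.0, sulfonic −1.0, phosphonic 2.0, tetrazole 4.9, aliphatic amine 10.6,
amidine 12.4, guanidine 13.6; keep-rules document aniline, pyridine, amide,
phenol and thiol). No per-compound pKa prediction and no tautomer
canonicalization is attempted; the rule engine is a stated approximation of
an expert manual curation, and users with expert-curated files should load
those instead.

## Descriptor panel

The reference panel is the 200 two-dimensional RDKit descriptors of the
2019-era releases. Later RDKit versions append descriptors (eight
`BCUT2D_*` terms, `AvgIpc`, `SPS`); these are excluded by a frozen set so
the panel and every named subset stay stable across backend versions, and
the backend version is recorded on every matrix. The `Ipc` graph-complexity
index grows combinatorially with molecule size and is divided by 1e41 at
computation time. Twelve element counts (nH, nB, nC, nN, nO, nS, nP, nF,
nCl, nBr, nI and the halogen total nX) extend the panel to 212 columns;
they are plain atom counts (implicit hydrogens included in nH) computed
directly with RDKit. Named subsets — FreeV11, FreeTV10, BloodV9, BloodTV11,
RDKit61, Large, Large212 — are frozen column lists selected in a fixed
order; selection is a pure projection.

Non-finite descriptor values (degenerate molecules) are imputed to 0 with a
warning: 0 is the panel's natural absent-feature value, and the affected
descriptors are count- or charge-like. Network inputs are max-normalized:
each column is divided by its maximum absolute value over the *training*
rows only, so held-out values may exceed 1; columns with zero training
maximum are left unchanged. Normalization constants are recorded for reuse.
Using training rows as the reference avoids information leaking from the
held-out partitions into the scaling; whether the original analysis
normalized over all rows is not recoverable, and this choice is the
conservative one.

## Scaffold split

Murcko scaffolds are computed without chirality; acyclic molecules share
the empty-string scaffold ("non-scaffold group"). The fixed split orders
groups by size descending, ties by descending first-member index (the
reference implementation's observed behaviour), and assigns groups whole:
to train while train stays within 0.8·N after the addition, then to
validation within 0.9·N, else to test. One degenerate guard: the first
group always opens train, so a single giant group cannot leave the training
partition empty. Equal inputs give identical splits.

Resampling for confidence intervals holds every multi-member group in train
and re-partitions the pooled singleton-scaffold molecules uniformly at
random to the reference split's partition sizes, seeded. Partition counts
are taken from the reference split, never hard-coded, so the procedure
generalizes beyond the original dataset. If the fixed benchmark split of a
dataset leaves multi-member groups in validation or test (common on small
synthetic sets), the resampler rejects it; `singleton_reference_split`
builds a compliant deterministic reference instead. The interval is a
Student-t interval on the mean, `mean ± t_{0.975, k−1}·s/√k`; at k = 100
the difference from a normal interval is negligible. Exactly identical
scores short-circuit to a zero-width interval to avoid floating-point
residue.

## Models

The random forest uses 90 trees of maximum depth 10 with scikit-learn
defaults otherwise (Gini impurity, sqrt feature subsampling — the library's
classifier default both then and now). With a fixed seed the forest is
fully deterministic, so repeated trials have standard deviation exactly 0
and scores print as e.g. `0.773(0)`; the trial runner therefore reuses the
base seed for forests and `base+i` for network trial i.

The network is three 256-unit hidden layers with a sigmoid output, batch
size 32, trained exactly 100 epochs with no early stopping. It is realized
with scikit-learn's `MLPClassifier` (relu activation, adam optimizer)
because neither SELU nor AdaMax is available in scikit-learn and no deep
learning framework is a dependency of this package; this substitution is
the package's largest deviation from the original description and is why
absolute network scores should be compared loosely. Scores are ROC-AUC via
scikit-learn, reported as `mean(std)` with the standard deviation expressed
in units of the last printed digit.

## Forward search and ensembling

Forward search scores every unselected descriptor by training a fresh model
on the current selection plus the candidate (training rows only) and
evaluating the criterion: ROC-AUC on validation rows, or on the pooled
train+validation predictions (`train_plus_validation`; an
averaged-two-scores variant is available behind `tv_mode="averaged"` since
the pooling convention is a judgment call). Candidate scores are averaged
over `repeats` seeded fits (default 3) because the network is stochastic.
A candidate is appended only if it improves the best score by at least
`epsilon` (default 0.001); two consecutive non-improving sweeps stop the
search as saturated, with a `max_steps` cap of 15 — searches on real data
plateau around nine to eleven descriptors. Ties in the argmax break toward
the earlier column, making the search deterministic given seeds. All row
access goes through a guard that raises on any attempt to read test rows,
so test contamination is an error, not a silent bias.

The ensemble is the elementwise n-th power mean of member probability
vectors with equal weights, default n = 1/32 (scores improve as n decreases
and saturate around 1/32); n = 1 is the arithmetic mean, and 0ⁿ = 0 handles
zero probabilities without singularity. Clipping (p < 0.02 → 0, p > 0.98 →
1) is applied after combination, matching its role as a final modification.
Clipping preserves ROC-AUC ordering except among the newly created ties at
0 and 1.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
medicinal chemistry. Molecules are assembled from 16 ring scaffolds
(benzene through morpholine, plus fused bicyclics) or acyclic chains (15%),
decorated with 1–5 substituents drawn from 18 common groups; phenyl/benzyl
substituents create combined scaffolds, giving ≥ 20 distinct Murcko
scaffolds at n ≥ 500 so scaffold splitting is meaningful. Labels are
Bernoulli in descriptor space: logit = 3.0 − 4.0·donors − 3.0·(MW−250)/100
+ 3.0·logP − 0.6·logP². The coefficients are deliberately large: the
emulated world is a *near-deterministic* Lipinski-like rule, keeping the
generator's Bayes rate high so that model tests measure pipeline
correctness rather than irreducible label noise. Molecules matching the
glucose motif — at least one aliphatic heterocycle and three or more
non-tertiary aliphatic hydroxyls — are instead positive with probability
0.9, mirroring carrier-mediated transport that a hydrophilicity rule
misses; motif molecules are built on a tetrahydropyran core with hydroxyls
on distinct ring carbons. The generator does not emulate: realistic
descriptor correlations, tautomers, stereochemistry, assay noise structure,
or the long-tailed scaffold distribution of real drug collections — so a
green model test establishes that the pipeline recovers planted structure,
not that real-data scores will match.

## Numerical conventions and limitations

- Unparseable SMILES raise typed errors carrying the offending string;
  curation flags rather than drops them.
- ROC-AUC requires both classes; single-class inputs raise instead of
  returning a default.
- Probabilities are validated to [0, 1] at ensemble boundaries.
- Scaffold-split property tests run on datasets of 100–400 molecules
  (rather than thousands) to keep the suite within a single-CPU budget; the
  properties checked are size-independent.
- Headline scores on the real curated datasets depend on the descriptor
  backend version and on the network substitution above; the package tracks
  them as soft regression checks through `bbbp.pipeline.headline_scores`,
  not as exact targets.
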