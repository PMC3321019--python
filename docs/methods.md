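# Methods

This note documents the models, rules, and design choices behind
`pinminer`, what the synthetic data does and does not emulate, and the
numerical conventions used throughout.

## Query model

A query is an ordered list of clauses, each a `(category, term,
operator)` triple with categories {disease, protein, go_term, tissue,
species, free_text} and operators {AND, OR, NOT}.  The first clause's
operator is AND by convention; NOT binds to its single following
clause; AND/OR are left-associative.  Ontology expansion is strictly
**one level down**: the matched node's synonyms plus names and synonyms
of direct `is_a`/`part_of` children.  Transitive descent is deliberately
excluded — repeated expansion of expansion members therefore never grows
past the one-level union, which the tests check as an idempotence
property.  Term matching into the ontology is case-insensitive on name
first, then synonyms, with ties broken by the lexicographically first
term id.  Species and free-text terms are never expanded (species names
are closed-class; free text is the user's escape hatch).

The serialized dialect is fixed by this package: every term is suffixed
with the configured field tag (default `[tw]`), multiword terms are
double-quoted, each clause is parenthesized, and clauses are joined by
their operators.  A round-trip parser (`parse_query`) exists solely to
verify the grammar is lossless.

## Corpus handling

Abstract retrieval is behind a two-method client contract
(`search(query, max_n, date_range) -> pmids`, `fetch(pmids) ->
records`); a replay client provides the contract offline and the live
NCBI client is opt-in only, so no test or batch run touches the
network.  MEDLINE parsing delegates to `Bio.Medline` (continuation
lines unfold with single spaces).  A record without an abstract body is
kept but flagged unprocessable.

Sentence splitting is rule-based: a boundary is a `.!?` followed by
whitespace and an upper-case/digit/opening character, suppressed after
a fixed abbreviation list (i.e., e.g., et al., Fig., vs., Dr., etc.,
...) and after single-letter initials.  No published splitting
algorithm is claimed; the list is short and documented in
`corpus.ABBREVIATIONS`.  The title is treated as sentence 0 and is
mined like any other sentence, since species detection and context
matching explicitly inspect titles.  Delimiter normalization flanks
`, ; :` with single spaces; a character map records, for every
preprocessed position, the raw offset it came from (None for inserted
spaces), so any tagged span can be traced to the original surface.
The operation is idempotent.

## Tagging rules

Protein tagging works on a length-preserving working copy of the
sentence in which every character outside `[A-Za-z0-9_]` becomes a
space, so offsets in the preprocessed text stay valid.  At each token
position the longest dictionary-matchable token span wins; matching is
case-sensitive for single-token entries (to avoid common lower-case
words) and case-insensitive for multi-token entries.  A match may then
absorb at most **two** right-adjacent tokens drawn from the
general-modifier set (`beta`, `alpha`, ...) or the head-noun set
(`receptor`, `kinase`, ...).  Mentions are non-overlapping, assigned
greedily left to right.  Dictionary cleaning at load time removes
common English words (a small bundled frequency list) and one-character
entries.  Equivalence with an exhaustive, index-free brute-force
matcher is asserted on 1000 generated sentences; ties between distinct
entries that normalize to the same token sequence resolve to the
lexicographically last entry in both implementations.

Interaction words and context terms match case-insensitively as whole
token sequences; hyphenated/inflected/spelling variants are explicit
lexicon entries mapping to a canonical word, which carries the
with-direction / without-direction flag.  Context terms are recorded at
both sentence scope and abstract scope (title + body + MeSH), so the
network layer can enforce either granularity.  MeSH terms are used for
species detection and context co-occurrence only — protein and
interaction tagging operate on sentences.

## Interaction and direction classifiers

Both classifiers are naive Bayes over six discrete features: token
distance between the proteins (0–2 / 3–5 / 6+), interaction-word
position (before / between / after the pair), intervening protein
mentions (0 / 1 / 2+), negation token within three tokens of the word,
comma between the proteins, and the word's inflection class (base /
-s / -ed / -ing / nominal).  This schema is this package's own
definition — a deliberately simple stand-in for richer published
feature sets — and is fixed for a model's lifetime.  Naive Bayes is a
Bayesian network with a fixed star structure; the structure is
pluggable behind the `TripletModel` contract should a richer dependency
graph ever be wanted.

Estimation is pure counting with Laplace smoothing (default α = 1);
for a value unseen in training, the feature's domain is enlarged by one
when normalizing, keeping posteriors proper.  Posteriors are computed
in log space and sum to 1 within 1e-9.  Training is order-insensitive;
the seed is recorded as metadata only.  Models serialize to versioned
JSON of the count tables.  A test cross-checks posteriors against
scikit-learn's `CategoricalNB` on shared domains; scikit-learn is never
the implementation.

Direction is only predicted for words flagged with-direction, after
the interaction threshold has been applied.  P(LR) + P(RL) = 1; an
exact tie at 0.5 resolves to LR — the majority class in curated
direction data, where active-voice order dominates — and is flagged
low-confidence.  Words missing from the lexicon are treated as
without-direction with a logged warning rather than an error.

Cross-validation is stratified k-fold (unstratified fallback with a
warning when a class has fewer than k members), reporting per-class
precision, recall, F and ROC area (rank statistic of the pooled
out-of-fold posterior), all as percentages.

## Normalization cascade

Resolution order: (1) case-sensitive exact match over the five catalog
fields in priority order official symbol → synonym → full name → other
symbol → locus tag; (2) case-insensitive repeat; (3) for each surface
variant in rule order (digit join, receptor abbreviation, one trailing
general-ending strip), repeat (1) then (2).  The first field with ≥ 1
hit decides; multiple hits there are reported as ambiguous with all
gene ids; no hit anywhere leaves the id blank and the node keyed by its
surface.  Search is restricted to the taxa detected in the abstract
(title, body, MeSH, first-occurrence order); when none is detected a
configurable default taxon applies (fixtures default: human, 9606).
Multiple detected taxa are searched as a union, with cross-taxon ties
reported as ambiguous.  Full-name matching is exact string equality —
stricter than a tokenized match, and noted as such.  The ending-strip
rule removes at most one trailing listed token per variant.

## Network conventions

Node identity is the official symbol when resolved, otherwise the
verbatim surface; ambiguous names keep all gene ids as a node
attribute.  Each retained interaction is one edge, so repeated findings
become parallel edges (multiplicity = literature support).  Directed
edges are stored actor → target (an RL call therefore stores
second-protein → first-protein); without-direction interactions are
single edges marked undirected.  Neighbor counts use distinct adjacent
nodes; percent coverage divides by the total node count including the
protein itself, reported to two decimals.  Hubs are nodes with ≥ 2
distinct neighbors.  Ties in all summary tables break alphabetically.
Raising the probability threshold can only shrink the network, and the
sentence-granularity edge set is always contained in the
document-granularity edge set — both are asserted over random networks.

The bundled asthma worked-example edge list covers only hub-incident
edges (its source presents it that way), so only quantities derivable
from those nine rows are asserted against it: IL4's three neighbors,
GRP's two, and the single doubled pair (IL17A–IL13).

## Synthetic data: what it emulates and what it does not

`fixtures` generates: a two-taxon gene catalog (14 human, 6 mouse
genes; one ambiguous synonym shared by two genes per taxon), a protein
dictionary consistent with the catalog, a 12-verb interaction lexicon
(6 with-direction, 6 without) with inflected/hyphenated variants,
species name index, two-level toy OBO ontologies, and MEDLINE corpora
built from fixed sentence templates with exact planted offsets:
positives in active voice (LR), passive voice (RL), and symmetric form
(NONE); negatives as negated relations, relations whose interaction
word falls outside the pair, and bare co-mentions; plus variant
surfaces (`SYM+`, `SYM beta`) and lowercase case-traps at configured
rates.  Default corpus: 20 abstracts, 1–2 positives each, each negative
kind at rate 0.5 (traps 0.3, variants 0.3, passives 0.25) — small
enough to hand-check, large enough that every template kind occurs.

The default labeled training sets are 100 true : 280 false interaction
triplets (≈ 1:2.8, mirroring the curated-data class balance this kind
of classifier is trained under) and 116 LR : 29 RL direction examples
(≈ 4:1, likewise).  Because the templates are fully separable under
the six-feature schema, cross-validated F reaches 100 % and planted
networks are recovered exactly; a label-permutation control confirms
ROC falls to ~50 %.  **These numbers validate the machinery, not
real-text performance**: real abstracts have coordination, anaphora,
nested clauses and dictionary noise that the templates deliberately do
not model, so measured fixture performance is an upper bound and no
claim about accuracy on PubMed text.

## Numerical and degenerate-input conventions

Posterior normalization tolerance 1e-9; default reporting threshold
0.95 (case-study style analyses may prefer 0.99 for precision or 0.85
for recall; the fixture recovery runs at 0.5, the classifier's natural
decision boundary).  Empty corpus → empty outputs with a warning; zero
search hits → empty list, not an error; empty dictionary/catalog →
no mentions / unresolved, not errors; zero query clauses or an empty
expansion → errors.  All generators and the pipeline are deterministic
given a seed: repeated runs produce byte-identical TSV outputs.

Problem sizes used by the acceptance script — 1000 oracle sentences,
380/145-row training sets, a 2000-row permutation control, a 20-abstract
recovery corpus, 100 random networks — are the package's default study
conditions and complete in a few seconds.
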