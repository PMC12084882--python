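# riboaudit

Sequence auditing, site liftover, and correction of rRNA chains in
ribosome structure models.

Deposited rabbit (*Oryctolagus cuniculus*) ribosome models disagree with
one another in their 28S/18S/5.8S/5S rRNA sequences: single-nucleotide
variants inherited from human, boar or yeast starting models, a +1
register shift in one common 18S numbering, and two bases (G183, C1513)
missing from the 1982 rabbit 18S RefSeq altogether. `riboaudit` makes the
audit reproducible for structural biologists and curators:

* extract each rRNA chain (with author numbering and modified-residue
  parent mapping) from an mmCIF or legacy PDB file;
* align it globally, with affine gap penalties, to a curated reference
  template — canonically the Broad Institute OryCun2.0 rabbit assembly via
  its RNA Central entries;
* catalogue every discrepancy: substitution columns (the headline
  "single-nucleotide changes" count, `100·matches/columns` identity under
  two gap conventions), insertion/deletion runs, and
  modified-but-unmappable residues, in 1-based template coordinates;
* lift functional-site numbering (A-site G626/C1331/A1825, P-site
  U1248/C1701, diagnostics G183/C1513 and h18 G613/C614) between
  numbering schemes, and detect register offsets;
* emit a sequence-corrected, template-renumbered mmCIF with a full change
  log — substitutions relabelled to the template base (base-specific atoms
  of the old base dropped and logged), indels flagged unresolved, never
  resolved by fabricating residues.

See `docs/methods.md` for the model, conventions and their rationale.

## Worked example

Generate a synthetic "deposited model" — an 18S-length chain with three
planted substitutions and a +1 numbering offset — then audit and correct
it:

```sh
$ riboaudit simulate --length 1869 --subs 3 --offset 1 --seed 11 --out demo
wrote reference.fasta, model.cif, truth.json to demo

$ riboaudit audit demo/model.cif --registry demo/reference.fasta
model_id  chain_id  reference_id            n_substitutions  n_insertion_runs  n_deletion_runs  n_modified_unknown  identity_gap_excluded  identity_gap_included (headline)
SYNTH     A         synth_18S_1869nt_seed11  3               0                 0                0                   99.84                  99.84
# single-nucleotide changes: min 3, max 3 across 1 chain(s)

$ riboaudit correct demo/model.cif --chain A --registry demo/reference.fasta \
      --out demo/corrected.cif --log demo/changes.tsv
corrected SYNTH/A against synth_18S_1869nt_seed11: 3 relabel(s), 1872 change-log entr(ies); re-audit: 0 substitution(s), 0 unresolved indel run(s)
```

The audit recovered exactly the three planted changes (identity
100·1866/1869 = 99.84%, identical under both gap conventions because the
alignment has no gaps). The correction relabelled those three bases and
renumbered all 1869 residues back by one (3 + 1869 = 1872 change-log
entries); re-auditing the corrected file confirms a clean chain. With real
models the same commands take the deposited mmCIF and a FASTA of the
reference templates (`riboaudit fetch --manifest --out refs/` downloads
the curated accessions on a networked machine); chains are assigned to
templates automatically by alignment identity.

Other entry points: `riboaudit sites` tabulates functional-site numbering
across every loaded scheme, and `riboaudit liftover` translates individual
positions between two schemes, reporting positions lost to indels as
`unmapped`. Everything is also available as a library
(`riboaudit.audit_chain`, `riboaudit.site_table`, ...).

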