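# Supplementary homolog tables (user-supplied)

Two acceptance checks and the `t3` target of `scripts/acceptance.py`
are defined over two externally published supplementary tables: the
N-terminal-domain (4,6-dehydratase) homolog list and the
C-terminal-domain (3,5-epimerase-4-reductase) homolog list. They are
not redistributable with this repository.

To enable those checks, convert the published XLS tables to
tab-separated files here:

- `table_s4.tsv` — N-terminal-domain homolog list
- `table_s5.tsv` — C-terminal-domain homolog list

Each file needs a header row with at least these columns:

- `gi` — the sequence identifier (GenBank gi number)
- `taxonomy` — the taxonomy string/rank for the entry

All other columns are ignored.
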