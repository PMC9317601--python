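# Packaged reference tables

These TSV files transcribe the summary tables of a published ensemble-docking
virtual-screening benchmark on the human TRPM8 homotetramer: 50 MD frames
(25–1250 ns, one every 25 ns), four monomers (A–D), docking of 1000 ligands
(20 actives / 980 decoys) scored by three primary docking scores (PS, CS,
CSopt), screened both on the frames as extracted ("raw") and after side-chain
optimization ("opt").

- `frames_raw.tsv`, `frames_opt.tsv` — per-frame best consensus equation and
  validated EF1% (status rows read "The frame was fully discarded").
  The transcription is verbatim: typographic variants of the printed
  equations (`CSBestA`, `CSoptmeanB`, `CSoptmeanD`, `CSoptbestC`, the bare
  score token in `CbestA`, Unicode minus signs, `nd`/`Nd` status markers)
  are preserved exactly; normalization happens at parse time.
- `term_frequency_raw.tsv`, `term_frequency_opt.tsv` — published
  best/mean term-occurrence counts per monomer and the per-monomer mean
  pocket volumes (Å³).
- `segment_summary.tsv` — EF1% means and pocket-volume averages over five
  250 ns trajectory segments (labels use an en dash, e.g. `25–250`).
- `multiframe_summary.tsv` — best EF1% and top-20-model mean EF1% of the
  multi-frame consensus analyses, per channel-subset selector.
- `metrics_comparison.tsv` — headline early-recognition and classification
  metrics of the multi-frame models next to a prior single-structure study.

All files are UTF-8, tab-separated, "." decimal separator. They are consumed
by `efoscreen.io.load_reference_table` and by the reference-table analyses;
no numeric value is altered from the printed source.
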