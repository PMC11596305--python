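# External inputs (not redistributed)

Some acceptance checks compare against published experimental inputs
that are not shipped with this repository and cannot be fetched in an
offline environment.  Placing the files below in this directory enables
those checks (`tests/test_acceptance.py`) and the corresponding targets
in `scripts/acceptance.py`.

| file | content | format |
| --- | --- | --- |
| `8QUP.pdb` | crystal structure of the grafted design | PDB fixed-column |
| `2D9Q.pdb` | native ligand:receptor complex | PDB fixed-column |
| `site_pairing_primary.tsv` | primary-site residue pairing | TSV: `chain_a res_a chain_b res_b` |
| `site_pairing_secondary.tsv` | secondary-site residue pairing | TSV: same columns |
| `spr_bv6.csv`, `spr_bop3.csv`, `spr_bv22.csv` | sensogram dilution series | CSV: `time_s, response_ru, concentration_M, phase{assoc,dissoc}` |
| `nfs60_bop1.csv`, `nfs60_bop3.csv`, `kasumi1_bop3.csv` | competitive-inhibition plate series | CSV: `concentration_M, response, role{sample,pos_ctrl,neg_ctrl}, replicate_id` |
| `bop1_mutations.tsv` | design mutation table | TSV: `position amino_acid` |
| `bv6_template.fasta`, `bop1.fasta` | template and design sequences | FASTA |

The PDB entries are available from the RCSB; the assay tables and the
mutation/sequence tables come from the publication's supplementary
material, converted to the CSV/TSV dialects above (one sheet per file).
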