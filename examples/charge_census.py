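"""Charged-residue census over a toy Rho-family-like alignment.

Counts K/R/H (positive) and D/E (negative) residues inside a membrane-
interface window defined in the reference sequence's own numbering, and
classifies each sequence's C-terminal tail as long or short.  The
alignment here is a hand-built synthetic stand-in, not real sequences.
"""

from memtether.seqcharge import InterfaceWindow, Msa, census_table

msa = Msa(
    (
        ("RHOD_LIKE", "MA-SGFRRLTQ--NVHTRRAQ---------"),
        ("RND1_LIKE", "MAQSGADSLTQ--NVSTAEAQLLNNTTRRA"),
        ("ACIDIC", "MD-EGFDELTQ--EVDTEEAQ---------"),
    )
)
window = InterfaceWindow("RHOD_LIKE", ((4, 9), (12, 16)))
records = census_table(
    msa, window, ref_catalytic_end=15, tail_threshold=4, excluded_ids=()
)
print(f"{'id':<10} {'n_pos':>5} {'n_neg':>5} {'tail':>4}  class")
for r in records:
    print(f"{r.id:<10} {r.n_pos:>5} {r.n_neg:>5} {r.tail_len:>4}  {r.tail_class}")
print("a basic patch (high n_pos, low n_neg) plus a short tail is the "
      "membrane-binding signature")
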