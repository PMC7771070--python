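"""Find DNA palindromes (inverted repeats) in a sequence window.

A DNA palindrome equals its own reverse complement — the hallmark of
transposon terminal repeats and REP elements.  This script scans a 120-nt
window around an insertion site for maximal palindromic subsequences.
"""

import hgtsite as h

window = (
    "AACAAGGAATTGGATTATAAAATTGTAAAAAGATAAGTTGAATATTCAACTTATCTTTTTA"
    "TTTCACGTCTATTTATCTTAAAACCTATTTTTTCTTCTATTTCTTTTAGCTGATTTTCA"
)

print("window length:", len(window))
for mode in ("strict", "center-gapped"):
    hits = h.find_palindromes(window, min_len=10, mode=mode)
    print(f"\n{mode} palindromes of >= 10 bp:")
    for hit in hits:
        sub = window[hit.start : hit.end]
        print(f"  [{hit.start:3d}, {hit.end:3d})  {sub}")

# the classic odd-length inverted repeat: palindromic up to its center base
print("\nCGTTGGCAACG strict:       ", h.is_palindromic("CGTTGGCAACG", "strict"))
print("CGTTGGCAACG center-gapped:", h.is_palindromic("CGTTGGCAACG", "center-gapped"))
# Each reported span is a maximal inverted repeat; the 36-mer in the middle
# of this window is a perfect strict palindrome.
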