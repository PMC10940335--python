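"""Build a small pedigree, compute additive relationships, and list the
family blocks over which the likelihood factorizes.

Expected output: parent-offspring and full-sib pairs share 0.5 of their
additive genetic variance, first cousins 0.125; the two household-linked
nuclear families merge into one likelihood block.
"""

from pedgxe import Pedigree, compute_kinship, family_blocks
from pedgxe.pedigree import Individual

ped = Pedigree([
    Individual("gpa", None, None, "male", "h1"),
    Individual("gma", None, None, "female", "h1"),
    Individual("dad", "gpa", "gma", "male", "h2"),
    Individual("aunt", "gpa", "gma", "female", "h3"),
    Individual("mom", None, None, "female", "h2"),
    Individual("uncle", None, None, "male", "h3"),
    Individual("kid", "dad", "mom", "female", "h2"),
    Individual("cousin", "uncle", "aunt", "male", "h3"),
])

kin = compute_kinship(ped)
print("2*phi parent-offspring (gpa, dad):", kin.loc["gpa", "dad"])
print("2*phi full sibs       (dad, aunt):", kin.loc["dad", "aunt"])
print("2*phi first cousins   (kid, cousin):", kin.loc["kid", "cousin"])
print("2*phi unrelated       (mom, uncle):", kin.loc["mom", "uncle"])

blocks = family_blocks(ped)
print(f"\n{len(blocks)} likelihood block(s):")
for b in blocks:
    print("  ", sorted(b))
print("Kinship and shared households connect everyone here, so the")
print("phenotypic covariance matrix has a single dense block.")
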