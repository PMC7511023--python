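"""From raw stereology counts to morphometric read-outs.

Shows the estimators on hand-tallied counts: a field with 64 reference
points of which 16 fell on septal tissue, and 20 test-line intersections
with the air-tissue interface.
"""

from alveomorph import FieldCounts, lm, lmw, summarize, sv_air, vv_sep

counts = [FieldCounts(p_nonpar=0, p_ref=64, p_sep=16, i_h=12, i_v=8)]

print(f"VVsep = {vv_sep(counts):.4f}   (sum Psep / sum Pref)")
print(f"Lm    = {lm(counts):.1f} um  (2 d (sum Pref - sum Psep) / sum I, d = 104 um)")
print(f"Lmw   = {lmw(counts):.1f} um  (2 d sum Psep / sum I)")
print(f"SVair = {sv_air(counts):.6f} /um (2 sum I / (d sum Pref))")

s = summarize(counts, subject_id="demo", lung_volume_um3=1.0e12)
print(
    f"\nwith a 1e12 um^3 lung: V_sep = {s.v_sep_um3:.3e} um^3, "
    f"S_air = {s.s_air_um2:.3e} um^2"
)
print(
    "\nA quarter of the parenchyma is septal tissue and the average\n"
    "airspace chord is ~0.5 mm — an emphysema-like, enlarged airspace."
)
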