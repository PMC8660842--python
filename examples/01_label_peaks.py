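"""Label molecules POS/NEG from UV-Vis peak lists.

A molecule is POS (photoreactive potential) when any listed absorption
maximum falls in 290-700 nm with MEC >= 1000 L/(mol cm). The example shows a
clear positive, a strong-but-too-blue negative, and a record whose MEC
values look like log-unit transcription errors.
"""

from photoreact.labeling import Peak, SpectrumRecord, label_spectrum

records = [
    SpectrumRecord("anthracene-like", (Peak(356.0, 8_000.0), Peak(252.0, 180_000.0))),
    SpectrumRecord("just-below-window", (Peak(282.0, 19_400.0),)),
    SpectrumRecord("suspect-log-units", (Peak(310.0, 4.2), Peak(265.0, 3.8))),
]

for rec in records:
    sc = label_spectrum(rec)
    print(f"{rec.mol_id:18s} label={sc.label} band={sc.pos_band:11s} "
          f"quality={sorted(sc.quality_flags)}")

# The first record is POS (356 nm peak, MEC 8000, band 5k-10k). The second is
# NEG despite its huge MEC: 282 nm is outside the window. The third is NEG
# but flagged suspect_log_mec: every MEC lies in [3, 5], the signature of
# log(MEC) values retrieved as MEC.
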