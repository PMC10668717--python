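"""The agreed sign-validation decision table as test records.

Each entry is (description, record, expected label) where the label is the
category after screening and table-level passes (C1/C2/C3/discarded).
"""

from conftest import make_sign

DECISION_TABLE = [
    # --- hard evidence (C1)
    ("live capture", make_sign(evidence_type="live_capture"), "C1"),
    ("rescued animal", make_sign(evidence_type="live_capture", expert_checked=True), "C1"),
    ("dead animal", make_sign(evidence_type="dead_animal"), "C1"),
    ("DNA-confirmed scat", make_sign(evidence_type="scat", dna_confirmed_wolf=True), "C1"),
    ("DNA-confirmed hair sample", make_sign(evidence_type="dna_sample", dna_confirmed_wolf=True), "C1"),
    ("DNA-confirmed urine", make_sign(evidence_type="dna_sample", dna_confirmed_wolf=True,
                                      genotype_label="G1"), "C1"),
    ("good-quality photo", make_sign(evidence_type="photo_video", photo_quality="good"), "C1"),
    ("good-quality video of pack", make_sign(evidence_type="photo_video", photo_quality="good",
                                             n_individuals=4), "C1"),
    ("telemetry location", make_sign(evidence_type="telemetry"), "C1"),
    # --- confirmed observations (C2)
    ("documented track 100 m (inclusive threshold)",
     make_sign(evidence_type="track", typical_pattern=True, track_length_m=100.0), "C2"),
    ("documented track 450 m",
     make_sign(evidence_type="track", typical_pattern=True, track_length_m=450.0), "C2"),
    ("scat checked by expert", make_sign(evidence_type="scat", expert_checked=True), "C2"),
    ("scat on a C2 track", make_sign(evidence_type="scat", on_c2_track=True), "C2"),
    ("kill with typical bites + other C2 data",
     make_sign(evidence_type="kill", typical_bites=True, combined_with_c2=True), "C2"),
    ("howl with pups checked by expert",
     make_sign(evidence_type="howl", pups_heard=True, expert_checked=True), "C2"),
    # --- unconfirmed observations (C3)
    ("track 80 m in snow",
     make_sign(evidence_type="track", typical_pattern=True, track_length_m=80.0, on_snow=True), "C3"),
    ("single footprint",
     make_sign(evidence_type="track", typical_pattern=False, track_length_m=0.5), "C3"),
    ("track without typical pattern",
     make_sign(evidence_type="track", typical_pattern=False, track_length_m=300.0), "C3"),
    ("scat not confirmed by expert", make_sign(evidence_type="scat", expert_checked=False), "C3"),
    ("heavily eaten kill", make_sign(evidence_type="kill", typical_bites=False), "C3"),
    ("kill not combined with other C2 data",
     make_sign(evidence_type="kill", typical_bites=True, combined_with_c2=False), "C3"),
    ("single howl", make_sign(evidence_type="howl", pups_heard=False), "C3"),
    ("howl with pups but no expert check",
     make_sign(evidence_type="howl", pups_heard=True, expert_checked=False), "C3"),
    ("unsupported sighting", make_sign(evidence_type="sighting"), "C3"),
    ("bad-quality picture", make_sign(evidence_type="photo_video", photo_quality="bad"), "C3"),
    ("DNA sample not confirming species",
     make_sign(evidence_type="dna_sample", dna_confirmed_wolf=False), "C3"),
    # --- discarded at screening
    ("no minimum technical description",
     make_sign(evidence_type="sighting", technically_documented=False), "discarded"),
    ("suspected deception",
     make_sign(evidence_type="photo_video", photo_quality="good", suspected_deception=True),
     "discarded"),
]

# isolate the records spatially so table-level context passes (kill
# corroboration, DNA-on-track) cannot link unrelated fixture rows
for _i, (_, _rec, _) in enumerate(DECISION_TABLE):
    _rec["x"] = 1000.0 + 100.0 * _i
    _rec["y"] = 1000.0
    _rec["sign_id"] = f"DT{_i:02d}"
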