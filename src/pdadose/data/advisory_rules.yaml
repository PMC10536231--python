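# Default exposure-tier advisory rules for chlorobenzene.
#
# Tier boundaries are ILLUSTRATIVE, not clinical guidance.  They are
# anchored to the reference scenario of 10 ppm inhaled 8 h/day for 14 days
# (1120 ppm·h over the window), which the occupational-toxicology
# literature links to a blood concentration of about 1 ug/mL.  Override
# with a custom rules file for any real deployment.
schema_version: 1
window_days: 14
tiers:
  - tier: 0
    name: minimal
    dose_low_ppmh: 0
    dose_high_ppmh: 80
    advice:
      - category: diet
        text: >-
          No action needed. Exposure over the window is below one day at the
          lowest calibrated concentration; maintain a balanced diet.
    citations: ["baseline tier (no exposure signal)"]
  - tier: 1
    name: elevated
    dose_low_ppmh: 80
    dose_high_ppmh: 1120
    advice:
      - category: diet
        text: >-
          Add cruciferous vegetables (broccoli, bok choy, cabbage) to the
          daily diet; about three cups of glucoraphanin-rich broccoli
          reaches the serum sulforaphane level shown to curb
          chlorobenzene-driven bone degradation.
      - category: OTC supplement
        text: >-
          Over-the-counter Vitamin D together with sulforaphane is as
          effective as prescription bisphosphonates against
          chlorobenzene-mediated osteoclast activation.
      - category: referral
        text: >-
          Share the logged exposure with an occupational-health contact if
          exposure persists at this level.
    citations: ["Vitamin D + sulforaphane OTC treatment evidence"]
  - tier: 2
    name: high
    dose_low_ppmh: 1120
    dose_high_ppmh: .inf
    advice:
      - category: diet
        text: >-
          Add cruciferous vegetables (broccoli, bok choy, cabbage) to the
          daily diet as a source of sulforaphane.
      - category: OTC supplement
        text: >-
          Take Vitamin D with sulforaphane; this OTC combination matches
          bisphosphonate efficacy against bone degradation in explant
          models.
      - category: prescription
        text: >-
          Discuss bisphosphonate therapy (e.g. alendronate) with a
          physician where accessible.
      - category: referral
        text: >-
          Cumulative exposure at or above 10 ppm x 8 h/day x 14 days
          (~1120 ppm·h) is associated with a blood concentration near
          1 ug/mL; refer to a physician or Occupational Health and Safety
          Administrator.
    citations:
      - "10 ppm (46 mg/m^3) x 8 h/day x 14 days -> ~1 ug/mL blood (literature value)"
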