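# Enzyme Commission numbers of the two composite community scores.
# Editable without code changes; keys are score names, values EC lists.
mucin_degradation:
  # functionally characterized mucin-active glycoside hydrolases
  - "3.2.1.169"  # protein O-GlcNAcase
  - "3.2.1.18"   # exo-alpha-sialidase
  - "3.2.1.23"   # beta-galactosidase
  - "3.2.1.49"   # alpha-N-acetylgalactosaminidase
  - "3.2.1.50"   # alpha-N-acetylglucosaminidase
  - "3.2.1.51"   # alpha-L-fucosidase
  - "3.2.1.52"   # beta-N-acetylhexosaminidase
oxidative_stress:
  # oxygen-detoxifying / oxidative-stress-response enzymes
  - "6.3.2.2"    # glutamate-cysteine ligase
  - "6.3.2.3"    # glutathione synthase
  - "1.8.1.7"    # glutathione-disulfide reductase
  - "1.15.1.1"   # superoxide dismutase
  - "1.11.1.15"  # peroxiredoxin
  - "1.8.4.11"   # peptide-methionine (S)-S-oxide reductase
  - "1.11.1.6"   # catalase
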