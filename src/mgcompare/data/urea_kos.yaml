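# Default KO identifier sets for the urea-processing screen.  Transport is
# satisfied by the complete five-subunit Urt ABC transporter OR the monomeric
# Utp urea channel; ureolysis requires the three structural urease subunits.
# Accessory (maturation) protein completeness is reported separately.
# Edit freely: the screen reads whatever sets this file defines.
urt_subunits:
  - K11959   # urtA
  - K11960   # urtB
  - K11961   # urtC
  - K11962   # urtD
  - K11963   # urtE
utp:
  - K08717   # SLC14A-family urea transporter homolog
urease_structural:
  - K01430   # ureA
  - K01429   # ureB
  - K01428   # ureC
urease_accessory:
  - K03187   # ureE
  - K03188   # ureF
  - K03189   # ureG
  - K03190   # ureD/ureH
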