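# Clinically conventional assignment of the 21 past-disease flags to organ
# systems ("scope" grouping), plus the set of diseases counted as severe
# invasive infections.  Both are configurable; this file covers every flag
# exactly once.
groups:
  pulmonology: [pneumonia, bronchitis, bronchiectasis, laryngitis]
  otorhinolaryngology: [otitis, sinusitis, urti, stomatitis, conjunctivitis]
  gastroenterology: [diarrhea, ibd, ascariasis]
  rheumatology: [arthritis, guillain_barre]
  resistance: [sepsis, meningitis, encephalitis, abscess, furunculosis, uti, hemophilia_a]
severe: [sepsis, meningitis, encephalitis, pneumonia]
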