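# Canonical alter taxonomy, version 1.
#
# Each category lists the raw labels that collapse into it.  Synonym sets
# must be disjoint; the loader rejects a table that maps one label to two
# categories.  Groups: HCP | non-HCP | self | media_internet.
version: 1
categories:
  - code: gp
    display_name: GP
    group: HCP
    synonyms:
      - general practitioner
      - family doctor
      - doctor
      - physician
      - local doctor
  - code: pharmacist
    display_name: Pharmacist
    group: HCP
    synonyms:
      - chemist
      - pharmacy
      - pharmacy assistant
  - code: allergist_immunologist
    display_name: Allergist/Immunologist
    group: HCP
    synonyms:
      - allergist
      - immunologist
      - allergy specialist
  - code: respiratory_specialist
    display_name: Respiratory specialist
    group: HCP
    synonyms:
      - respiratory physician
      - pulmonologist
      - lung specialist
  - code: ent_specialist
    display_name: ENT specialist
    group: HCP
    synonyms:
      - ent
      - ear nose and throat specialist
      - ear, nose and throat specialist
      - otolaryngologist
  - code: practice_nurse
    display_name: Practice nurse
    group: HCP
    synonyms:
      - nurse
  - code: other_hcp
    display_name: Other HCP
    group: HCP
    synonyms:
      - other hcps
      - dermatologist
      - neurologist
      - optometrist
      - ophthalmologist
      - opthalmologist
  - code: alternative_therapist
    display_name: Alternative therapist
    group: HCP
    synonyms:
      - naturopath
      - acupuncturist
      - homeopath
      - herbalist
  - code: parents_partner
    display_name: Parents/Partner
    group: non-HCP
    synonyms:
      - parent
      - parents
      - mother
      - father
      - mum
      - dad
      - partner
      - spouse
      - wife
      - husband
  - code: family
    display_name: Family
    group: non-HCP
    synonyms:
      - sibling
      - siblings
      - brother
      - sister
      - relative
      - relatives
      - cousin
  - code: friends_colleagues
    display_name: Friends/Colleagues
    group: non-HCP
    synonyms:
      - friend
      - friends
      - colleague
      - colleagues
      - workmate
      - co-worker
  - code: media
    display_name: Media
    group: media_internet
    synonyms:
      - television
      - tv
      - radio
      - newspaper
      - magazine
      - advertisement
      - advertising
  - code: internet
    display_name: Internet
    group: media_internet
    synonyms:
      - web
      - online
      - google
      - website
      - online forum
  - code: own_experience
    display_name: Own experience
    group: self
    synonyms:
      - my own experience
      - personal experience
      - experience
      - self
      - myself
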