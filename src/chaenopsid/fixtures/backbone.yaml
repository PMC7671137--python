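# Default backbone for the composite chaenopsid phylogeny.
#
# Genus-level relationships: the Neoclinus + Mccoskerichthys lineage is the
# sister group of the Chaenopsinae; within the Chaenopsinae, Coralliozetus is
# sister to all others, followed by the Protemblemaria clade (Protemblemaria,
# Cirriemblemaria, Emblemariopsis — internal resolution unknown, kept as a
# trichotomy), which is sister to Acanthemblemaria plus the "reef-sand clade"
# (Ekemblemaria + Hemiemblemaria, and the "Chaenopsis clade" holding
# Lucayablennius, Chaenopsis, and Emblemaria as a polytomy).
#
# Species within each genus default to a polytomy; the only named subgroup is
# the "caldwelli species group" inside Emblemaria.  The group is described as
# a four-species clade but only three members are identifiable and sampled;
# the fourth is unsampled (flagged here, see docs/methods.md).
backbone:
  name: root
  children:
    - name: neoclinus_lineage
      children:
        - genus: Neoclinus
        - genus: Mccoskerichthys
    - name: Chaenopsinae
      children:
        - genus: Coralliozetus
        - name: core_chaenopsinae
          children:
            - name: protemblemaria_clade
              children:
                - genus: Protemblemaria
                - genus: Cirriemblemaria
                - genus: Emblemariopsis
            - name: acanthemblemaria_plus_reef_sand
              children:
                - genus: Acanthemblemaria
                - name: reef_sand_clade
                  children:
                    - name: ekemblemaria_hemiemblemaria
                      children:
                        - genus: Ekemblemaria
                        - genus: Hemiemblemaria
                    - name: chaenopsis_clade
                      children:
                        - genus: Lucayablennius
                        - genus: Chaenopsis
                        - genus: Emblemaria
subgroups:
  Emblemaria:
    - name: caldwelli_group
      members:
        - Emblemaria caldwelli
        - Emblemaria caycedoi
        - Emblemaria hyltoni
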