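# Protonation rules for the dominant species at blood pH (~7.4).
#
# Each rule is a SMARTS substructure query; `site` is the index, within the
# match, of the atom gaining or losing a proton.  Rules are ordered and
# first-match-wins per site.  A deprotonate rule fires only when
# pka < pH - margin; a protonate rule only when pka > pH + margin; `keep`
# rules document groups deliberately left neutral and never transform.
# pKa values are general textbook values for the functional group class.
ph: 7.4
margin: 1.0
rules:
  - name: sulfonic-acid
    pattern: "[SX4](=O)(=O)[OX2H1]"
    site: 3
    pka: -1.0
    action: deprotonate
  - name: phosphonic-acid-first-proton
    pattern: "[PX4](=O)([OX2H1])"
    site: 2
    pka: 2.0
    action: deprotonate
  - name: carboxylic-acid
    pattern: "[CX3](=O)[OX2H1]"
    site: 2
    pka: 4.0
    action: deprotonate
  - name: tetrazole
    pattern: "[nX3H1]1nnnc1"
    site: 0
    pka: 4.9
    action: deprotonate
  - name: guanidine
    pattern: "[NX3][CX3](=[NX2])[NX3]"
    site: 2
    pka: 13.6
    action: protonate
  - name: amidine
    pattern: "[CX3;!$(C(N)(N)=N)](=[NX2])[NX3]"
    site: 1
    pka: 12.4
    action: protonate
  - name: aliphatic-amine
    pattern: "[NX3;H0,H1,H2;!$(Nc);!$(NC=[O,S,N]);!$(N[!#6;!#1]);!$(N=*);!$([N+]);!$(N#*)]"
    site: 0
    pka: 10.6
    action: protonate
  - name: aniline
    pattern: "[NX3;!$(NC=O)]c"
    site: 0
    pka: 4.6
    action: keep
  - name: pyridine
    pattern: "[nX2;$(n1ccccc1)]"
    site: 0
    pka: 5.2
    action: keep
  - name: amide-nh
    pattern: "[NX3][CX3]=[OX1]"
    site: 0
    pka: 0.0
    action: keep
  - name: phenol
    pattern: "[OX2H1]c"
    site: 0
    pka: 10.0
    action: keep
  - name: thiol
    pattern: "[SX2H1]"
    site: 0
    pka: 10.5
    action: keep
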