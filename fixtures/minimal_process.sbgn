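<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
  <map language="process description" id="minimal_process">
    <glyph id="sub" class="macromolecule">
      <label text="substrate"/>
      <bbox x="0" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="prc" class="process">
      <bbox x="140" y="0" w="20" h="20"/>
    </glyph>
    <glyph id="prd" class="macromolecule">
      <label text="product"/>
      <bbox x="0" y="90" w="80" h="40"/>
    </glyph>
    <arc id="a1" class="consumption" source="sub" target="prc">
      <start x="40" y="20"/>
      <end x="150" y="10"/>
    </arc>
    <arc id="a2" class="production" source="prc" target="prd">
      <start x="150" y="10"/>
      <end x="40" y="110"/>
    </arc>
  </map>
</sbgn>
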