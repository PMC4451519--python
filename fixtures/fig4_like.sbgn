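<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
  <map language="process description" id="fig4_like">
    <glyph id="cytosol" class="compartment">
      <label text="cytosol"/>
      <bbox x="0" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="rsk" class="macromolecule" compartmentRef="cytosol">
      <label text="RSK"/>
      <bbox x="140" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="rsk_p" class="macromolecule" compartmentRef="cytosol">
      <label text="RSK-p"/>
      <bbox x="280" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="rsk_pp" class="macromolecule" compartmentRef="cytosol">
      <label text="RSK-pp"/>
      <bbox x="0" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="erk" class="macromolecule" compartmentRef="cytosol">
      <label text="ERK"/>
      <bbox x="140" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="p1" class="process" compartmentRef="cytosol">
      <bbox x="280" y="90" w="20" h="20"/>
    </glyph>
    <glyph id="p2" class="process" compartmentRef="cytosol">
      <bbox x="0" y="180" w="20" h="20"/>
    </glyph>
    <arc id="a1" class="consumption" source="rsk" target="p1">
      <start x="180" y="20"/>
      <end x="290" y="100"/>
    </arc>
    <arc id="a2" class="production" source="p1" target="rsk_p">
      <start x="290" y="100"/>
      <end x="320" y="20"/>
    </arc>
    <arc id="a3" class="catalysis" source="erk" target="p1">
      <start x="180" y="110"/>
      <end x="290" y="100"/>
    </arc>
    <arc id="a4" class="consumption" source="rsk_p" target="p2">
      <start x="320" y="20"/>
      <end x="10" y="190"/>
    </arc>
    <arc id="a5" class="production" source="p2" target="rsk_pp">
      <start x="10" y="190"/>
      <end x="40" y="110"/>
    </arc>
  </map>
</sbgn>
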