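<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
  <map language="process description" id="fig2_like">
    <glyph id="muscle_cytosol" class="compartment">
      <label text="muscle cytosol"/>
      <bbox x="0" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="actin_myosin" class="complex" compartmentRef="muscle_cytosol">
      <label text="actin-myosin"/>
      <bbox x="140" y="0" w="80" h="40"/>
      <glyph id="actin" class="macromolecule">
        <label text="actin"/>
        <bbox x="0" y="90" w="80" h="40"/>
      </glyph>
      <glyph id="myosin_cx" class="complex">
        <label text="myosin complex"/>
        <bbox x="280" y="0" w="80" h="40"/>
        <glyph id="myosin" class="macromolecule">
          <label text="myosin"/>
          <bbox x="420" y="0" w="80" h="40"/>
        </glyph>
      </glyph>
    </glyph>
    <glyph id="e1" class="macromolecule" compartmentRef="muscle_cytosol">
      <label text="intermediate"/>
      <bbox x="140" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="e2" class="macromolecule" compartmentRef="muscle_cytosol">
      <label text="end product"/>
      <bbox x="280" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="enz" class="macromolecule" compartmentRef="muscle_cytosol">
      <label text="enzyme"/>
      <bbox x="420" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="f1" class="macromolecule" compartmentRef="muscle_cytosol">
      <label text="unrelated in"/>
      <bbox x="0" y="180" w="80" h="40"/>
    </glyph>
    <glyph id="f2" class="macromolecule" compartmentRef="muscle_cytosol">
      <label text="unrelated out"/>
      <bbox x="140" y="180" w="80" h="40"/>
    </glyph>
    <glyph id="p1" class="process" compartmentRef="muscle_cytosol">
      <bbox x="280" y="180" w="20" h="20"/>
    </glyph>
    <glyph id="p2" class="process" compartmentRef="muscle_cytosol">
      <bbox x="420" y="180" w="20" h="20"/>
    </glyph>
    <glyph id="p3" class="process" compartmentRef="muscle_cytosol">
      <bbox x="0" y="270" w="20" h="20"/>
    </glyph>
    <arc id="a1" class="consumption" source="myosin_cx" target="p1">
      <start x="320" y="20"/>
      <end x="290" y="190"/>
    </arc>
    <arc id="a2" class="production" source="p1" target="e1">
      <start x="290" y="190"/>
      <end x="180" y="110"/>
    </arc>
    <arc id="a3" class="consumption" source="e1" target="p2">
      <start x="180" y="110"/>
      <end x="430" y="190"/>
    </arc>
    <arc id="a4" class="production" source="p2" target="e2">
      <start x="430" y="190"/>
      <end x="320" y="110"/>
    </arc>
    <arc id="a5" class="catalysis" source="enz" target="p2">
      <start x="460" y="110"/>
      <end x="430" y="190"/>
    </arc>
    <arc id="a6" class="consumption" source="f1" target="p3">
      <start x="40" y="200"/>
      <end x="10" y="280"/>
    </arc>
    <arc id="a7" class="production" source="p3" target="f2">
      <start x="10" y="280"/>
      <end x="180" y="200"/>
    </arc>
  </map>
</sbgn>
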