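<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
  <map language="process description" id="fig1_like">
    <glyph id="nbn1" class="macromolecule">
      <label text="NBN"/>
      <bbox x="0" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="nbn2" class="macromolecule">
      <label text="NBN"/>
      <bbox x="140" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="atm" class="macromolecule">
      <label text="ATM"/>
      <bbox x="280" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="atm_p" class="macromolecule">
      <label text="ATM-p"/>
      <bbox x="420" y="0" w="80" h="40"/>
    </glyph>
    <glyph id="chk" class="macromolecule">
      <label text="CHK2"/>
      <bbox x="0" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="chk_p" class="macromolecule">
      <label text="CHK2-p"/>
      <bbox x="140" y="90" w="80" h="40"/>
    </glyph>
    <glyph id="mrn" class="complex">
      <label text="MRN"/>
      <bbox x="280" y="90" w="80" h="40"/>
      <glyph id="mre11" class="macromolecule">
        <label text="MRE11"/>
        <bbox x="0" y="180" w="80" h="40"/>
      </glyph>
      <glyph id="nbn_m" class="macromolecule">
        <label text="NBN"/>
        <bbox x="420" y="90" w="80" h="40"/>
      </glyph>
      <glyph id="rad50" class="macromolecule">
        <label text="RAD50"/>
        <bbox x="140" y="180" w="80" h="40"/>
      </glyph>
    </glyph>
    <glyph id="p1" class="process">
      <bbox x="280" y="180" w="20" h="20"/>
    </glyph>
    <glyph id="p2" class="association">
      <bbox x="420" y="180" w="20" h="20"/>
    </glyph>
    <glyph id="p3" class="process">
      <bbox x="0" y="270" w="20" h="20"/>
    </glyph>
    <glyph id="p4" class="process">
      <bbox x="140" y="270" w="20" h="20"/>
    </glyph>
    <arc id="a1" class="consumption" source="nbn1" target="p1">
      <start x="40" y="20"/>
      <end x="290" y="190"/>
    </arc>
    <arc id="a2" class="production" source="p1" target="atm_p">
      <start x="290" y="190"/>
      <end x="460" y="20"/>
    </arc>
    <arc id="a3" class="consumption" source="atm" target="p1">
      <start x="320" y="20"/>
      <end x="290" y="190"/>
    </arc>
    <arc id="a4" class="consumption" source="nbn1" target="p2">
      <start x="40" y="20"/>
      <end x="430" y="190"/>
    </arc>
    <arc id="a5" class="consumption" source="nbn2" target="p2">
      <start x="180" y="20"/>
      <end x="430" y="190"/>
    </arc>
    <arc id="a6" class="production" source="p2" target="mrn">
      <start x="430" y="190"/>
      <end x="320" y="110"/>
    </arc>
    <arc id="a7" class="consumption" source="nbn2" target="p3">
      <start x="180" y="20"/>
      <end x="10" y="280"/>
    </arc>
    <arc id="a8" class="production" source="p3" target="chk">
      <start x="10" y="280"/>
      <end x="40" y="110"/>
    </arc>
    <arc id="a9" class="consumption" source="chk" target="p4">
      <start x="40" y="110"/>
      <end x="150" y="280"/>
    </arc>
    <arc id="a10" class="production" source="p4" target="chk_p">
      <start x="150" y="280"/>
      <end x="180" y="110"/>
    </arc>
    <arc id="a11" class="catalysis" source="mrn" target="p4">
      <start x="320" y="110"/>
      <end x="150" y="280"/>
    </arc>
  </map>
</sbgn>
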