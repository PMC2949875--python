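((t1:15.036194433638983,(t2:2.0382127484629513,t3:2.0382127484629513):12.997981685176029):32.193805566361014,(((((t4:3.9829697168306213,t5:3.9829697168306213):4.0824809891920495,((t6:6.678211839073686,t7:6.678211839073686):0.20991293956200657,(t8:6.2318338471006,(t9:3.2442906107465124,(t10:0.37895435444448206,t11:0.37895435444448206):2.8653362563020304):2.9875432363540875):0.6562909315350931):1.1773259273869778):17.27021015993124,((t12:6.966939698272348,t13:6.966939698272348):15.791830212950174,t14:22.75876991122251):2.57689095473139):15.395368705179425,((t15:10.821748450231278,(t16:4.236104998197692,t17:4.236104998197692):6.585643452033585):25.122489087308704,((t18:18.615963548362267,t19:18.615963548362267):4.234282113832353,(t20:17.09247020055895,((t21:0.5883917893317231,t22:0.5883917893317231):2.1812761042115243,t23:2.7696678935432475):14.322802307015701):5.757775461635671):13.09399187534537):4.786792033593352):6.107753027467874,(((((((t24:2.9989947399931993,t25:2.9989947399931993):0.1805316735562397,t26:3.1795264135494383):9.156171122222876,t27:12.335697535772317):2.9495701365944695,t28:15.285267672366784):13.776580598750277,(((t29:8.34713196791014,((t30:3.026990453478719,(t31:2.1001828759102845,t32:2.1001828759102845):0.9268075775684352):2.1801790639344087,t33:5.207169517413129):3.1399624504970136):6.682104262748801,(t34:15.019552946020847,t35:15.019552946020847):0.009683284638099865):11.482382964943307,((t36:4.273887430340796,t37:4.273887430340796):13.978520310578736,((t38:2.866949901468427,(t39:1.6636854793710552,t40:1.6636854793710552):1.203264422097372):11.373262682984727,t41:14.240212584453158):4.012195156466379):8.259211454682719):2.55022907551481):7.084648270953913,(t42:25.355426379888282,(((t43:20.388577806733394,t44:20.388577806733394):3.7143192594183394,(t45:13.259253589838764,(t46:11.977063249711366,t47:11.977063249711366):1.2821903401273942):10.843643476312986):0.7130279260140129,(((t48:12.861880467195023,t49:12.861880467195023):5.420859078165255,t50:18.282739545360272):5.470952044481537,(t51:9.647517426998315,t52:9.647517426998315):14.106174162843493):1.0622334023239492):0.53950138772254):10.791070162182677):2.703564886690219,((t53:5.195320105913883,t54:5.195320105913883):10.464765769320845,(t55:2.635617208784843,(t56:2.5921215424130457,t57:2.5921215424130457):0.04349566637179761):13.024468666449888):23.189975553526462):7.988721169840021):0.39121740139877925);
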